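"""Nuclear genotype frequencies from duplexed qPCR ΔCt measurements.

A heterokaryotic mycelium carries two nuclear genotypes: the fusion
mutant, whose deleted locus is replaced by a hygromycin-resistance
cassette (*hygB* amplicon), and the wild type, whose intact locus is
amplified by the *so* primer pair. Each genomic-DNA sample is assayed in
technical replicates per amplicon; replicate Ct values are averaged and
the Ct difference converted into a template-abundance ratio through the
per-cycle amplification efficiency E:

    ΔCt = mean Ct(so) − mean Ct(hygB)
    r   = E**ΔCt              (hygB-template : so-template ratio)
    f   = r / (1 + r)         (frequency of mutant nuclei)

The sign convention means a positive ΔCt (the *so* amplicon crossing
threshold later) reflects more mutant template: ΔCt = 0 gives 50/50,
ΔCt = 2 at E = 2 gives 80/20. Ct values at the cycle ceiling (no
amplification) yield a censored frequency of 0 or 1 rather than a number
computed from E raised to ±max cycles.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_MAX_CYCLES = 40.0
DEFAULT_EFFICIENCY = 2.0

CENSORED_ALL_MUTANT = "censored_all_mutant"
CENSORED_ALL_WT = "censored_all_wt"


class ReplicateScatterWarning(UserWarning):
    """Technical replicates scatter more than the configured threshold."""


@dataclasses.dataclass(frozen=True)
class CtMeasurement:
    """Technical-replicate Ct values of one gDNA sample, both amplicons."""

    sample: str
    ct_so: tuple[float, ...]
    ct_hygB: tuple[float, ...]
    max_cycles: float = DEFAULT_MAX_CYCLES

    def __post_init__(self) -> None:
        for name, values in (("ct_so", self.ct_so), ("ct_hygB", self.ct_hygB)):
            if len(values) == 0:
                raise ValueError(f"{name} replicate list is empty for sample {self.sample!r}")
            for v in values:
                if not (0.0 < v <= self.max_cycles):
                    raise ValueError(
                        f"Ct value {v} of {name} outside (0, {self.max_cycles}] "
                        f"for sample {self.sample!r}"
                    )


@dataclasses.dataclass(frozen=True)
class FrequencyEstimate:
    """Frequency of mutant (Δso) and wild-type nuclei in one sample.

    ``delta_ct`` is the averaged Ct difference the estimate is based on
    (``nan`` for censored samples); ``flag`` marks censoring.
    """

    f_dso: float
    delta_ct: float
    flag: str | None = None

    @property
    def f_wt(self) -> float:
        return 1.0 - self.f_dso


def aggregate_ct(
    replicates: Sequence[float],
    sd_warn_threshold: float = 0.5,
) -> tuple[float, float, int]:
    """Average technical replicates; returns (mean, sd, n).

    Emits :class:`ReplicateScatterWarning` when the replicate standard
    deviation exceeds ``sd_warn_threshold`` cycles — a sign of pipetting
    or amplification trouble, not a hard error.
    """
    if len(replicates) == 0:
        raise ValueError("cannot aggregate an empty replicate list")
    arr = np.asarray(replicates, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    if sd > sd_warn_threshold:
        warnings.warn(
            f"replicate SD {sd:.3f} exceeds {sd_warn_threshold} cycles",
            ReplicateScatterWarning,
            stacklevel=2,
        )
    return mean, sd, int(arr.size)


def frequency_from_delta_ct(
    delta_ct: float,
    efficiency: float = DEFAULT_EFFICIENCY,
) -> FrequencyEstimate:
    """Convert an averaged Ct difference into a mutant-nucleus frequency.

    ``delta_ct`` is mean Ct(so) − mean Ct(hygB); ``efficiency`` is the
    per-cycle amplification factor (2.0 = perfect doubling). Strictly
    increasing in ``delta_ct`` with f(−Δ) = 1 − f(Δ).
    """
    if efficiency <= 1.0:
        raise ValueError(f"amplification efficiency must exceed 1, got {efficiency}")
    r = efficiency**delta_ct
    return FrequencyEstimate(f_dso=r / (1.0 + r), delta_ct=float(delta_ct))


def frequency_from_ct_pair(
    mean_ct_so: float,
    mean_ct_hygB: float,
    efficiency_so: float = DEFAULT_EFFICIENCY,
    efficiency_hygB: float = DEFAULT_EFFICIENCY,
) -> FrequencyEstimate:
    """Generalised conversion with per-amplicon efficiencies.

    Template abundance is proportional to E^−Ct per amplicon, so the
    mutant:wild-type ratio is r = E_hygB^−Ct(hygB) / E_so^−Ct(so).
    With equal efficiencies this reduces to r = E^ΔCt.
    """
    if efficiency_so <= 1.0 or efficiency_hygB <= 1.0:
        raise ValueError("amplification efficiencies must exceed 1")
    log_r = mean_ct_so * math.log(efficiency_so) - mean_ct_hygB * math.log(efficiency_hygB)
    r = math.exp(log_r)
    return FrequencyEstimate(f_dso=r / (1.0 + r), delta_ct=float(mean_ct_so - mean_ct_hygB))


def frequency_from_measurement(
    m: CtMeasurement,
    efficiency: float = DEFAULT_EFFICIENCY,
    sd_warn_threshold: float = 0.5,
) -> FrequencyEstimate:
    """Averaged-ΔCt frequency estimate for one measurement.

    A sample whose *so* replicates all sit at the cycle ceiling shows no
    wild-type amplification: the frequency is censored to 1 (all mutant).
    Symmetrically, *hygB* at the ceiling censors to 0.
    """
    so_ceiling = all(v >= m.max_cycles for v in m.ct_so)
    hyg_ceiling = all(v >= m.max_cycles for v in m.ct_hygB)
    if so_ceiling and hyg_ceiling:
        raise ValueError(f"sample {m.sample!r}: no amplification on either amplicon")
    if so_ceiling:
        return FrequencyEstimate(f_dso=1.0, delta_ct=math.nan, flag=CENSORED_ALL_MUTANT)
    if hyg_ceiling:
        return FrequencyEstimate(f_dso=0.0, delta_ct=math.nan, flag=CENSORED_ALL_WT)

    mean_so, _, _ = aggregate_ct(m.ct_so, sd_warn_threshold)
    mean_hyg, _, _ = aggregate_ct(m.ct_hygB, sd_warn_threshold)
    return frequency_from_delta_ct(mean_so - mean_hyg, efficiency)


def read_ct_table(path: str) -> list[CtMeasurement]:
    """Read a long-format TSV with columns sample, amplicon, replicate, ct.

    ``amplicon`` must be ``so`` or ``hygB``.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "amplicon", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns: {sorted(missing)}")
    bad = set(df["amplicon"].unique()) - {"so", "hygB"}
    if bad:
        raise ValueError(f"unknown amplicon labels: {sorted(bad)}")
    out = []
    for sample, grp in df.groupby("sample", sort=True):
        out.append(
            CtMeasurement(
                sample=str(sample),
                ct_so=tuple(grp.loc[grp["amplicon"] == "so", "ct"].astype(float)),
                ct_hygB=tuple(grp.loc[grp["amplicon"] == "hygB", "ct"].astype(float)),
            )
        )
    return out


def process_ct_table(
    measurements: Sequence[CtMeasurement],
    efficiency: float = DEFAULT_EFFICIENCY,
) -> pd.DataFrame:
    """Per-sample frequency table from a batch of measurements.

    Columns: sample, mean_ct_so, mean_ct_hygB, delta_ct, f_dso, f_wt, flag.
    """
    rows = []
    for m in measurements:
        est = frequency_from_measurement(m, efficiency)
        mean_so = float(np.mean(m.ct_so))
        mean_hyg = float(np.mean(m.ct_hygB))
        rows.append(
            {
                "sample": m.sample,
                "mean_ct_so": mean_so,
                "mean_ct_hygB": mean_hyg,
                "delta_ct": est.delta_ct,
                "f_dso": est.f_dso,
                "f_wt": est.f_wt,
                "flag": est.flag or "",
            }
        )
    return pd.DataFrame(rows)
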