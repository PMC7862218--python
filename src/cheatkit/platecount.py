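"""Genotype frequencies from selective-plating colony counts.

Two strains carrying complementary auxotrophic markers (*inl*,
inositol-requiring; *pan*, pantothenate-requiring) and their
heterokaryons are distinguished by plating the spore suspension on three
media:

- +inositol plates grow *inl*-deficient homokaryons **and** heterokaryons;
- +pantothenate plates grow *pan*-deficient homokaryons **and** heterokaryons;
- unsupplemented plates grow heterokaryons only (the two nuclear types
  complement each other's deficiency).

Colony counts are converted to spore concentrations, the heterokaryon
concentration read off the unsupplemented plates, subtracted from the two
supplemented media to get the homokaryon concentrations, and normalised
to frequencies. Heterokaryons are assumed to plate with equal efficiency
on all three media. Sampling noise can make the unsupplemented count
exceed a supplemented one; the resulting negative homokaryon estimate is
clipped to zero and flagged, and a constrained Poisson maximum-likelihood
mode is available for noisy counts.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize


@dataclasses.dataclass(frozen=True)
class PlateCountTriple:
    """Pooled colony counts and plating factors for the three media.

    ``dilution_*`` is the fold-dilution of the plated suspension and
    ``volume_*`` the plated volume in ml (replicate plates pooled by
    summing counts and volumes before construction).
    """

    count_inl: int
    count_pan: int
    count_none: int
    dilution_inl: float = 1.0
    dilution_pan: float = 1.0
    dilution_none: float = 1.0
    volume_inl: float = 1.0
    volume_pan: float = 1.0
    volume_none: float = 1.0

    def __post_init__(self) -> None:
        for name in ("count_inl", "count_pan", "count_none"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in (
            "dilution_inl",
            "dilution_pan",
            "dilution_none",
            "volume_inl",
            "volume_pan",
            "volume_none",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def concentrations(self) -> tuple[float, float, float]:
        """(c_inl, c_pan, c_none) in spores/ml."""
        return (
            concentration(self.count_inl, self.dilution_inl, self.volume_inl),
            concentration(self.count_pan, self.dilution_pan, self.volume_pan),
            concentration(self.count_none, self.dilution_none, self.volume_none),
        )


@dataclasses.dataclass(frozen=True)
class GenotypeFrequencies:
    """Frequencies of the two homokaryon classes and heterokaryons.

    ``clipped`` is True when a negative homokaryon estimate was clipped
    to zero before renormalisation.
    """

    f_inl_homokaryon: float
    f_pan_homokaryon: float
    f_heterokaryon: float
    clipped: bool = False

    def __post_init__(self) -> None:
        total = self.f_inl_homokaryon + self.f_pan_homokaryon + self.f_heterokaryon
        if not np.isclose(total, 1.0):
            raise ValueError(f"frequencies must sum to 1, got {total}")
        for f in (self.f_inl_homokaryon, self.f_pan_homokaryon, self.f_heterokaryon):
            if f < 0:
                raise ValueError("frequencies must be non-negative")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.f_inl_homokaryon, self.f_pan_homokaryon, self.f_heterokaryon)


def concentration(count: int, dilution_factor: float, volume_plated: float) -> float:
    """Spores/ml from a colony count: count × dilution / volume.

    Replicate plates pool exactly: summing counts and volumes gives the
    same value as averaging per-plate concentrations at equal volumes.
    """
    if count < 0:
        raise ValueError("colony count must be non-negative")
    if dilution_factor <= 0 or volume_plated <= 0:
        raise ValueError("dilution factor and plated volume must be positive")
    return count * dilution_factor / volume_plated


def deconvolve_genotypes(t: PlateCountTriple, method: str = "subtract") -> GenotypeFrequencies:
    """Estimate genotype frequencies from a plate-count triple.

    ``method="subtract"`` (default) applies the exact algebra of the
    plating design: c_het = c_none, c_inl_homo = c_inl − c_none,
    c_pan_homo = c_pan − c_none. Negative intermediates are clipped to 0
    and flagged. ``method="mle"`` maximises the Poisson likelihood of the
    three observed counts over non-negative class concentrations, which
    cannot go negative and is preferable for noisy counts.
    """
    c_inl, c_pan, c_none = t.concentrations
    if c_inl == 0 and c_pan == 0 and c_none == 0:
        raise ValueError("all three concentrations are zero; frequencies undefined")
    if method == "subtract":
        c_het = c_none
        c_inl_homo = c_inl - c_none
        c_pan_homo = c_pan - c_none
        clipped = c_inl_homo < 0 or c_pan_homo < 0
        c_inl_homo = max(c_inl_homo, 0.0)
        c_pan_homo = max(c_pan_homo, 0.0)
    elif method == "mle":
        c_inl_homo, c_pan_homo, c_het = _poisson_mle(t)
        clipped = False
    else:
        raise ValueError(f"unknown method {method!r}")
    total = c_inl_homo + c_pan_homo + c_het
    if total == 0:
        raise ValueError("all class concentrations are zero after clipping")
    return GenotypeFrequencies(
        f_inl_homokaryon=c_inl_homo / total,
        f_pan_homokaryon=c_pan_homo / total,
        f_heterokaryon=c_het / total,
        clipped=clipped,
    )


def _poisson_mle(t: PlateCountTriple) -> tuple[float, float, float]:
    """Poisson MLE of (c_inl_homo, c_pan_homo, c_het) concentrations.

    Expected counts: inl plates see c_inl_homo + c_het, pan plates see
    c_pan_homo + c_het, unsupplemented plates see c_het, each scaled by
    volume/dilution.
    """
    counts = np.array([t.count_inl, t.count_pan, t.count_none], dtype=float)
    scale = np.array(
        [
            t.volume_inl / t.dilution_inl,
            t.volume_pan / t.dilution_pan,
            t.volume_none / t.dilution_none,
        ]
    )

    def neg_loglik(theta: np.ndarray) -> float:
        ci, cp, ch = theta
        mu = np.array([ci + ch, cp + ch, ch]) * scale
        mu = np.maximum(mu, 1e-12)
        return float(np.sum(mu - counts * np.log(mu)))

    # subtraction estimate (clipped) seeds the optimiser
    c_inl, c_pan, c_none = t.concentrations
    x0 = np.maximum([c_inl - c_none, c_pan - c_none, c_none], 1e-6)
    res = optimize.minimize(
        neg_loglik, x0, method="L-BFGS-B", bounds=[(0, None)] * 3
    )
    return tuple(float(v) for v in res.x)


def phenotype_frequency(
    mutant_colonies: int,
    wildtype_colonies: int,
    realized_initial_frequency: float | None = None,
) -> tuple[float, tuple[float, float] | None]:
    """Mutant frequency from phenotype-scored colony counts.

    Returns ``(f_mutant, pairing)`` where ``pairing`` is
    ``(realized_initial_frequency, f_mutant)`` ready for the fitness
    stage — the *realized* (plate-estimated), not nominal, initial
    frequency is what competitive success must be computed against.
    """
    if mutant_colonies < 0 or wildtype_colonies < 0:
        raise ValueError("colony counts must be non-negative")
    total = mutant_colonies + wildtype_colonies
    if total == 0:
        raise ValueError("no colonies counted; frequency undefined")
    f_mutant = mutant_colonies / total
    pairing = None
    if realized_initial_frequency is not None:
        if not (0.0 <= realized_initial_frequency <= 1.0):
            raise ValueError("realized initial frequency must lie in [0, 1]")
        pairing = (realized_initial_frequency, f_mutant)
    return f_mutant, pairing


def process_count_table(path_or_df, method: str = "subtract") -> pd.DataFrame:
    """Deconvolve a long-format count table, one row per plate.

    Expects columns sample, transfer, medium ∈ {inl, pan, none}, count,
    dilution, volume; replicate plates are pooled per (sample, transfer,
    medium) by summing counts and volumes. Returns one row per
    (sample, transfer) with the three frequencies and a clip flag.
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df, sep="\t")
    required = {"sample", "transfer", "medium", "count", "dilution", "volume"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count table is missing columns: {sorted(missing)}")
    rows = []
    for (sample, transfer), grp in df.groupby(["sample", "transfer"], sort=True):
        pooled: dict[str, tuple[int, float, float]] = {}
        for medium, mg in grp.groupby("medium"):
            if len(mg["dilution"].unique()) != 1:
                raise ValueError(
                    f"{sample}/{transfer}/{medium}: replicate plates at different "
                    "dilutions cannot be pooled by summing"
                )
            pooled[medium] = (
                int(mg["count"].sum()),
                float(mg["dilution"].iloc[0]),
                float(mg["volume"].sum()),
            )
        missing_media = {"inl", "pan", "none"} - set(pooled)
        if missing_media:
            raise ValueError(f"{sample}/{transfer}: missing media {sorted(missing_media)}")
        triple = PlateCountTriple(
            count_inl=pooled["inl"][0],
            count_pan=pooled["pan"][0],
            count_none=pooled["none"][0],
            dilution_inl=pooled["inl"][1],
            dilution_pan=pooled["pan"][1],
            dilution_none=pooled["none"][1],
            volume_inl=pooled["inl"][2],
            volume_pan=pooled["pan"][2],
            volume_none=pooled["none"][2],
        )
        freqs = deconvolve_genotypes(triple, method=method)
        rows.append(
            {
                "sample": sample,
                "transfer": transfer,
                "f_inl_homokaryon": freqs.f_inl_homokaryon,
                "f_pan_homokaryon": freqs.f_pan_homokaryon,
                "f_heterokaryon": freqs.f_heterokaryon,
                "clip_flag": freqs.clipped,
            }
        )
    return pd.DataFrame(rows)
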