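"""Synthetic inputs for every stage of the pipeline, with known truth.

Each generator is the forward model of its analysis stage and reduces to
an exact inverse in the noise-free limit:

- :func:`simulate_alignments` emulates paired-end sequencing of a clone
  carrying a large deletion: reads spanning a breakpoint carry soft
  clips, pairs straddling the deletion lose the proper-pair flag, and a
  truth table records the breakpoint windows.
- :func:`simulate_qpcr_ct` draws technical-replicate Ct values whose
  mean ΔCt equals log_E(f/(1−f)) at the true mutant-nucleus frequency f.
- :func:`simulate_plate_counts` draws multinomial colony counts from the
  selective-plating design at known genotype frequencies.
- :func:`simulate_transfer_series` iterates a serial-transfer regime:
  deterministic selection through a phenomenological success function
  S(f), heterokaryon formation at a configured per-cycle rate, a spore
  yield declining with cheater frequency, then a binomial/multinomial
  bottleneck at a configured transfer fraction.

The transfer-cycle success function is an explicit stand-in: a
log-linear S(f) with a root at a configurable equilibrium frequency,
chosen to echo negative frequency dependence, not derived from any
mechanistic model of mycelial growth. All stochastic output is
reproducible from (config, seed) alone.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from cheatkit.platecount import GenotypeFrequencies, PlateCountTriple
from cheatkit.qpcr import CtMeasurement
from cheatkit.svscan import AlignmentObservation, tile_windows

# SAM flags used by the read simulator: proper pairs and pairs that lost
# the proper-pair bit (the straddling-pair signature).
FLAG_PROPER_R1, FLAG_PROPER_R2 = 99, 147
FLAG_DISC_R1, FLAG_DISC_R2 = 97, 145


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for all generators.

    Defaults mirror the experimental design being emulated: ~30× paired
    -end coverage with a 300 bp deletion implanted in a small reference;
    six qPCR technical replicates with 0.1-cycle Gaussian noise at
    doubling efficiency; four plates per medium at ~400 colonies each;
    serial transfers of 1% of total spores every cycle, four transfers,
    starting the cheater at 10%. The success function is
    S(f) = exp(selection_strength × (equilibrium_frequency − f)).
    """

    seed: int = 0
    # read simulation
    contig: str = "contig_sim"
    reference_length: int = 5000
    read_length: int = 100
    mean_depth: float = 30.0
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    deletion: tuple[int, int] | None = (1000, 300)  # (start, length), 0-based
    background_clip_rate: float = 0.01
    window: int = 100
    # qPCR
    ct_noise_sd: float = 0.1
    efficiency: float = 2.0
    base_ct: float = 20.0
    max_cycles: float = 40.0
    n_ct_replicates: int = 6
    # plating
    true_frequencies: tuple[float, float, float] = (0.55, 0.35, 0.10)
    colonies_per_plate: int = 400
    n_plates: int = 4
    # transfer series
    initial_cheater_frequency: float = 0.10
    equilibrium_frequency: float = 0.30
    selection_strength: float = 3.0
    het_formation_rate: float = 0.20
    yield_max: float = 2.0e8
    yield_decline: float = 0.5
    bottleneck_fraction: float = 0.01
    n_transfers: int = 4

    def __post_init__(self) -> None:
        if not (0.0 < self.bottleneck_fraction <= 1.0):
            raise ValueError("bottleneck_fraction must lie in (0, 1]")
        if abs(sum(self.true_frequencies) - 1.0) > 1e-9:
            raise ValueError("true_frequencies must sum to 1")
        if self.deletion is not None:
            start, length = self.deletion
            if start < 0 or length <= 0 or start + length >= self.reference_length:
                raise ValueError("deletion must fit strictly inside the reference")
        if self.read_length <= 0 or self.reference_length <= 0:
            raise ValueError("read_length and reference_length must be positive")
        if self.deletion is not None and self.reference_length - self.deletion[1] < 2 * self.read_length:
            raise ValueError("reference too short for paired reads after excising the deletion")


def load_config(path: str) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "deletion" in raw and raw["deletion"] is not None:
        raw["deletion"] = tuple(raw["deletion"])
    if "true_frequencies" in raw:
        raw["true_frequencies"] = tuple(raw["true_frequencies"])
    return SimulationConfig(**raw)


def _resolve_seed(cfg: SimulationConfig, seed: int | None) -> int:
    return cfg.seed if seed is None else seed


# ---------------------------------------------------------------------------
# read-alignment simulation


def _map_donor_pos(pos: int, del_start: int, del_len: int) -> int:
    """Donor (deletion-excised) coordinate → reference coordinate."""
    return pos if pos < del_start else pos + del_len


def _read_alignment(
    donor_start: int,
    read_length: int,
    del_start: int | None,
    del_len: int,
) -> tuple[int, str]:
    """(reference position, CIGAR) of one donor read.

    A read whose donor interval crosses the excision point aligns in two
    pieces; the longer piece anchors the alignment and the shorter is
    soft-clipped, as a breakpoint-spanning read maps in practice.
    """
    if del_start is None or not (donor_start < del_start < donor_start + read_length):
        ref_pos = donor_start if del_start is None else _map_donor_pos(donor_start, del_start, del_len)
        return ref_pos, f"{read_length}M"
    left = del_start - donor_start
    right = read_length - left
    if left >= right:
        return donor_start, f"{left}M{right}S"
    return del_start + del_len, f"{left}S{right}M"


def simulate_alignments(
    cfg: SimulationConfig,
    seed: int | None = None,
    out_sam: str | None = None,
) -> tuple[list[AlignmentObservation], pd.DataFrame]:
    """Paired-end alignments of a clone, with breakpoint truth table.

    Fragments are drawn uniformly from the donor genome (the reference
    with the configured deletion excised; no deletion for an ancestor
    clone) at the configured depth, error-free. Reads spanning an
    excision point get soft-clipped CIGARs; pairs straddling it keep
    their positions but lose the proper-pair flag (flags 97/145).
    A configurable background rate adds small terminal soft clips to
    otherwise normal reads.

    Returns the mapped reads as :class:`AlignmentObservation` records and
    a truth table of windows overlapping the implanted breakpoints
    (empty for an ancestor). ``out_sam`` additionally writes a SAM text
    file, byte-identical for identical (config, seed).
    """
    rng = np.random.default_rng(_resolve_seed(cfg, seed))
    rl = cfg.read_length
    if cfg.deletion is not None:
        del_start, del_len = cfg.deletion
    else:
        del_start, del_len = None, 0
    donor_length = cfg.reference_length - del_len
    n_pairs = max(1, round(cfg.mean_depth * donor_length / (2 * rl)))

    records: list[tuple] = []  # (qname, flag, pos, mapq, cigar, mate_pos, tlen)
    observations: list[AlignmentObservation] = []
    for i in range(n_pairs):
        frag = int(round(rng.normal(cfg.insert_mean, cfg.insert_sd)))
        frag = max(frag, 2 * rl)
        frag = min(frag, donor_length)
        start = int(rng.integers(0, donor_length - frag + 1))
        d1, d2 = start, start + frag - rl

        pos1, cig1 = _read_alignment(d1, rl, del_start, del_len)
        pos2, cig2 = _read_alignment(d2, rl, del_start, del_len)

        straddles = (
            del_start is not None
            and d1 + rl <= del_start
            and d2 >= del_start
        )
        f1, f2 = (FLAG_DISC_R1, FLAG_DISC_R2) if straddles else (FLAG_PROPER_R1, FLAG_PROPER_R2)

        if del_start is None and cfg.background_clip_rate > 0:
            for which in (1, 2):
                if rng.random() < cfg.background_clip_rate:
                    clip = 5
                    if which == 1:
                        cig1 = f"{rl - clip}M{clip}S"
                    else:
                        cig2 = f"{rl - clip}M{clip}S"
        elif del_start is not None and cfg.background_clip_rate > 0:
            if rng.random() < cfg.background_clip_rate:
                cig1 = f"{rl - 5}M5S" if "S" not in cig1 else cig1

        span_end = max(pos1 + rl, pos2 + rl)
        tlen = span_end - min(pos1, pos2)
        qname = f"sim_pair_{i:07d}"
        records.append((qname, f1, pos1, 60, cig1, pos2, tlen))
        records.append((qname, f2, pos2, 60, cig2, pos1, -tlen))

    records.sort(key=lambda r: (r[2], r[0], r[1]))
    for qname, flag, pos, mapq, cigar, mate_pos, tlen in records:
        observations.append(
            AlignmentObservation(
                flag=flag,
                contig=cfg.contig,
                pos=pos,
                cigar=_parse_cigar(cigar),
                mapq=mapq,
            )
        )

    truth = _breakpoint_truth(cfg, del_start, del_len)

    if out_sam is not None:
        _write_sam(out_sam, cfg, records)
    return observations, truth


def _parse_cigar(cigar: str) -> tuple[tuple[str, int], ...]:
    out = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((ch, int(num)))
            num = ""
    return tuple(out)


def _breakpoint_truth(
    cfg: SimulationConfig, del_start: int | None, del_len: int
) -> pd.DataFrame:
    cols = ["contig", "breakpoint", "window_start", "window_end"]
    if del_start is None:
        return pd.DataFrame(columns=cols)
    windows = tile_windows(cfg.reference_length, cfg.window)
    rows = []
    # a window is breakpoint-adjacent when its interval touches the
    # breakpoint: clip-anchored coverage accumulates on either side
    for bp in (del_start, del_start + del_len):
        for ws, we in windows:
            if ws <= bp <= we:
                rows.append({"contig": cfg.contig, "breakpoint": bp, "window_start": ws, "window_end": we})
    return pd.DataFrame(rows, columns=cols).drop_duplicates().reset_index(drop=True)


def _write_sam(path: str, cfg: SimulationConfig, records: list[tuple]) -> None:
    rl = cfg.read_length
    seq = "A" * rl  # error-free simulation: base identity carries no signal
    qual = "I" * rl
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{cfg.contig}\tLN:{cfg.reference_length}\n")
        for qname, flag, pos, mapq, cigar, mate_pos, tlen in records:
            fh.write(
                f"{qname}\t{flag}\t{cfg.contig}\t{pos + 1}\t{mapq}\t{cigar}\t"
                f"=\t{mate_pos + 1}\t{tlen}\t{seq}\t{qual}\n"
            )


# ---------------------------------------------------------------------------
# qPCR simulation


def simulate_qpcr_ct(
    true_f_dso: float,
    efficiency: float = 2.0,
    noise_sd: float = 0.1,
    n_replicates: int = 6,
    seed: int | None = None,
    base_ct: float = 20.0,
    max_cycles: float = 40.0,
    sample: str = "sim",
) -> CtMeasurement:
    """Ct replicates whose noise-free ΔCt is log_E(f/(1−f)).

    Each amplicon's Ct reflects its template share: Ct = base −
    log_E(share), plus Gaussian replicate noise. At the boundary
    frequencies 0 and 1 the missing template's amplicon is censored at
    the cycle ceiling.
    """
    if not (0.0 <= true_f_dso <= 1.0):
        raise ValueError("true_f_dso must lie in [0, 1]")
    if efficiency <= 1.0:
        raise ValueError("efficiency must exceed 1")
    rng = np.random.default_rng(seed)

    def cts(share: float) -> tuple[float, ...]:
        if share <= 0.0:
            return tuple([max_cycles] * n_replicates)
        mean = base_ct - math.log(share) / math.log(efficiency)
        vals = mean + rng.normal(0.0, noise_sd, size=n_replicates) if noise_sd > 0 else np.full(n_replicates, mean)
        return tuple(float(min(max(v, 1e-6), max_cycles)) for v in vals)

    return CtMeasurement(
        sample=sample,
        ct_hygB=cts(true_f_dso),
        ct_so=cts(1.0 - true_f_dso),
        max_cycles=max_cycles,
    )


# ---------------------------------------------------------------------------
# plating simulation


def simulate_plate_counts(
    true_frequencies: Sequence[float] | GenotypeFrequencies,
    colonies_per_plate: int = 400,
    n_plates: int = 4,
    seed: int | None = None,
    exact: bool = False,
) -> PlateCountTriple:
    """Colony counts of the three-media plating design at known truth.

    ``true_frequencies`` is (f_inl_homokaryon, f_pan_homokaryon,
    f_heterokaryon). Each plate receives ``colonies_per_plate`` spores
    whose genotypes are multinomial draws; a spore forms a colony on a
    medium iff its class is viable there. ``exact=True`` replaces the
    draws with expected counts (rounded), making the deconvolution's
    subtraction algebra an exact inverse when the expectations are
    integral. Replicate plates are pooled by summing counts and volumes.
    """
    if isinstance(true_frequencies, GenotypeFrequencies):
        f_inl, f_pan, f_het = true_frequencies.as_tuple()
    else:
        f_inl, f_pan, f_het = (float(x) for x in true_frequencies)
    if abs(f_inl + f_pan + f_het - 1.0) > 1e-9 or min(f_inl, f_pan, f_het) < 0:
        raise ValueError("true frequencies must be non-negative and sum to 1")
    if colonies_per_plate <= 0 or n_plates <= 0:
        raise ValueError("colonies_per_plate and n_plates must be positive")

    rng = np.random.default_rng(seed)
    probs = np.array([f_inl, f_pan, f_het])
    counts = {"inl": 0, "pan": 0, "none": 0}
    for medium in ("inl", "pan", "none"):
        for _ in range(n_plates):
            if exact:
                n_i, n_p, n_h = probs * colonies_per_plate
            else:
                n_i, n_p, n_h = rng.multinomial(colonies_per_plate, probs)
            if medium == "inl":
                viable = n_i + n_h
            elif medium == "pan":
                viable = n_p + n_h
            else:
                viable = n_h
            counts[medium] += int(round(viable))
    vol = float(n_plates)
    return PlateCountTriple(
        count_inl=counts["inl"],
        count_pan=counts["pan"],
        count_none=counts["none"],
        volume_inl=vol,
        volume_pan=vol,
        volume_none=vol,
    )


# ---------------------------------------------------------------------------
# serial-transfer simulation


def success_function(f: float, cfg: SimulationConfig) -> float:
    """Phenomenological competitive success of the cheater at frequency f.

    log S is linear in f with root at ``cfg.equilibrium_frequency``:
    S > 1 below the equilibrium, S < 1 above. A stand-in for the real
    (unmodelled) growth dynamics, not a mechanistic claim.
    """
    return math.exp(cfg.selection_strength * (cfg.equilibrium_frequency - f))


def simulate_transfer_series(
    cfg: SimulationConfig,
    seed: int | None = None,
    infinite_population: bool = False,
    n_transfers: int | None = None,
) -> pd.DataFrame:
    """Serial-transfer trajectory of cheater/wild-type/heterokaryon classes.

    Per cycle: (1) deterministic selection — the cheater-homokaryon class
    is weighted by S(f) at the current cheater nuclear frequency f
    (heterokaryons and wild type weight 1); (2) heterokaryon formation
    moves ``het_formation_rate × 2 f_c f_w`` of the population from the
    homokaryon classes into the heterokaryon class; (3) total spore
    yield ``yield_max × (1 − yield_decline × f)``; (4) a multinomial
    bottleneck of ``bottleneck_fraction`` of the yield seeds the next
    cycle (skipped in ``infinite_population`` mode).

    Returns one row per transfer (row 0 = initial state) with class
    frequencies, cheater nuclear frequency (heterokaryons counted half),
    spore yield and a termination flag.
    """
    rng = np.random.default_rng(_resolve_seed(cfg, seed))
    n_cycles = cfg.n_transfers if n_transfers is None else n_transfers
    f_c = cfg.initial_cheater_frequency
    f_w = 1.0 - f_c
    f_h = 0.0

    rows = [
        {
            "transfer": 0,
            "f_cheater_homokaryon": f_c,
            "f_wt_homokaryon": f_w,
            "f_heterokaryon": f_h,
            "f_cheater_nuclear": f_c + 0.5 * f_h,
            "spore_yield": math.nan,
            "terminated": False,
        }
    ]
    terminated = False
    for t in range(1, n_cycles + 1):
        if terminated:
            break
        f_nuc = f_c + 0.5 * f_h
        s = success_function(f_nuc, cfg)
        weights = np.array([f_c * s, f_w, f_h])
        total_w = weights.sum()
        if total_w == 0:
            terminated = True
            break
        f_c, f_w, f_h = weights / total_w

        formed = cfg.het_formation_rate * 2.0 * f_c * f_w
        formed = min(formed, 2.0 * min(f_c, f_w))
        f_c -= formed / 2.0
        f_w -= formed / 2.0
        f_h += formed

        f_nuc = f_c + 0.5 * f_h
        spore_yield = cfg.yield_max * max(0.0, 1.0 - cfg.yield_decline * f_nuc)

        if not infinite_population:
            n_transferred = int(round(cfg.bottleneck_fraction * spore_yield))
            if n_transferred <= 0:
                terminated = True
            else:
                draw = rng.multinomial(n_transferred, [f_c, f_w, f_h])
                f_c, f_w, f_h = draw / n_transferred

        rows.append(
            {
                "transfer": t,
                "f_cheater_homokaryon": f_c,
                "f_wt_homokaryon": f_w,
                "f_heterokaryon": f_h,
                "f_cheater_nuclear": f_c + 0.5 * f_h,
                "spore_yield": spore_yield,
                "terminated": terminated,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# competition-assay simulation (inputs for the fitness stage)


def simulate_competitions(
    cfg: SimulationConfig,
    initial_frequencies: Sequence[float],
    n_replicates: int = 3,
    count_total: int = 300,
    seed: int | None = None,
) -> list:
    """Competition records with S(f) given by the configured success function.

    For each nominal starting frequency, per replicate: the realized
    initial frequency is estimated from a binomial phenotype count of
    ``count_total`` colonies, one growth cycle multiplies the cheater's
    odds by S(f), and the final frequency is again a binomial count —
    the same two-plating protocol the fitness stage assumes.
    """
    from cheatkit.fitness import CompetitionRecord

    rng = np.random.default_rng(_resolve_seed(cfg, seed))
    records = []
    for f0 in initial_frequencies:
        if not (0.0 < f0 < 1.0):
            raise ValueError("initial frequencies must lie in (0, 1)")
        for rep in range(n_replicates):
            realized = rng.binomial(count_total, f0) / count_total
            if realized in (0.0, 1.0):
                continue
            s = success_function(realized, cfg)
            odds = s * realized / (1.0 - realized)
            f_true_final = odds / (1.0 + odds)
            observed_final = rng.binomial(count_total, f_true_final) / count_total
            records.append(
                CompetitionRecord(
                    replicate=f"f{f0:.3f}_r{rep}",
                    f_initial=realized,
                    f_final=observed_final,
                )
            )
    return records
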