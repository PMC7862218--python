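"""Pairwise ancestor-vs-evolved variant difference filtering.

Per-clone VCF call sets (e.g. VarScan mpileup2cns output) are compared
site by site between an ancestor and an evolved clone. A difference is
reported when the alternate-allele frequency changed by at least
``min_freq_diff`` (default 0.8) and the site is covered by at least
``min_cov`` reads (default 10). A call present in only one sample is
treated as frequency 0 in the other, with the depth taken from the
sample that carries the record. Multi-allelic records are decomposed
into one row per alternate allele before comparison.

Heterokaryotic samples — mixtures of two nuclear genotypes — produce
intermediate allele frequencies that this filter deliberately drops;
:func:`intermediate_frequency_report` surfaces those calls separately
instead of relaxing the thresholds.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

try:
    from cyvcf2 import VCF
except ImportError:  # pragma: no cover
    VCF = None

GAINED = "gained"
LOST = "lost"


@dataclasses.dataclass(frozen=True)
class VariantCall:
    """One biallelic variant call: site, alleles, depth and frequency."""

    contig: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    depth: int
    alt_frequency: float

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError(f"depth must be non-negative, got {self.depth}")
        if not (0.0 <= self.alt_frequency <= 1.0):
            raise ValueError(f"alt_frequency must lie in [0, 1], got {self.alt_frequency}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


def _format_or_none(variant, field: str):
    try:
        return variant.format(field)
    except KeyError:
        return None


def _varscan_freq(variant) -> float | None:
    """Parse the VarScan FORMAT FREQ percentage field ("85.5%")."""
    raw = _format_or_none(variant, "FREQ")
    if raw is None:
        return None
    txt = raw[0]
    if isinstance(txt, (bytes, np.bytes_)):
        txt = txt.decode()
    try:
        return float(str(txt).rstrip("%")) / 100.0
    except ValueError:
        return None


def _frequency_from_record(variant, alt_index: int, freq_field: str | None) -> float:
    """Alt-allele frequency of one decomposed alt, first sample.

    Default: alt-supporting depth / DP from FORMAT AD. Fallbacks:
    VarScan-style FORMAT FREQ ("85.5%"), then INFO AF.
    """
    if freq_field == "FREQ":
        val = _varscan_freq(variant)
        if val is None:
            raise ValueError("FORMAT FREQ requested but absent or unparseable")
        return val

    ad = _format_or_none(variant, "AD")
    dp = _depth_from_record(variant)
    if ad is not None and dp > 0:
        ad_row = np.asarray(ad[0]).ravel()
        # htslib convention is AD = ref,alt1,...; VarScan writes alt depth only
        if ad_row.size >= len(variant.ALT) + 1:
            return float(ad_row[1 + alt_index]) / dp
        return float(ad_row[min(alt_index, ad_row.size - 1)]) / dp

    val = _varscan_freq(variant)
    if val is not None:
        return val

    af = variant.INFO.get("AF")
    if af is not None:
        if isinstance(af, tuple):
            return float(af[alt_index])
        return float(af)
    raise ValueError(
        f"no usable frequency field at {variant.CHROM}:{variant.POS} "
        "(tried FORMAT AD/DP, FORMAT FREQ, INFO AF)"
    )


def _depth_from_record(variant) -> int:
    try:
        dp = variant.format("DP")
        if dp is not None:
            return int(np.asarray(dp[0]).ravel()[0])
    except KeyError:
        pass
    dp = variant.INFO.get("DP")
    if dp is not None:
        return int(dp)
    return 0


def read_vcf(path: str, freq_field: str | None = None) -> list[VariantCall]:
    """Read a VCF 4.x into decomposed biallelic :class:`VariantCall` rows.

    ``freq_field``: None (default, alt depth/DP with fallbacks) or
    ``"FREQ"`` to force the VarScan percentage field.
    """
    if VCF is None:  # pragma: no cover
        raise ImportError("cyvcf2 is required to read VCF files")
    calls: list[VariantCall] = []
    vcf = VCF(path)
    for variant in vcf:
        depth = _depth_from_record(variant)
        for i, alt in enumerate(variant.ALT):
            try:
                freq = _frequency_from_record(variant, i, freq_field)
            except ValueError as exc:
                raise ValueError(f"line for {variant.CHROM}:{variant.POS}: {exc}") from exc
            calls.append(
                VariantCall(
                    contig=variant.CHROM,
                    pos=variant.POS,
                    ref=variant.REF,
                    alt=alt,
                    depth=depth,
                    alt_frequency=min(max(freq, 0.0), 1.0),
                )
            )
    vcf.close()
    return calls


def pairwise_diff(
    calls_ancestor: list[VariantCall],
    calls_evolved: list[VariantCall],
    min_cov: int = 10,
    min_freq_diff: float = 0.8,
    cov_mode: str = "both",
) -> pd.DataFrame:
    """Filtered ancestor/evolved variant differences.

    A row is reported when |freq_evolved − freq_ancestor| ≥
    ``min_freq_diff`` (inclusive) and the coverage requirement holds:
    with ``cov_mode="both"`` (default) the depth at the site must reach
    ``min_cov`` in both samples (an absent call inherits the carrying
    sample's depth); ``cov_mode="carrier"`` only requires it in the
    sample(s) with a record. Direction is ``gained`` when the evolved
    frequency is higher, ``lost`` otherwise.

    Returns a DataFrame with columns contig, pos, ref, alt,
    freq_ancestor, freq_evolved, depth, direction, sorted by site.
    """
    if cov_mode not in ("both", "carrier"):
        raise ValueError(f"cov_mode must be 'both' or 'carrier', got {cov_mode!r}")
    anc = {c.key: c for c in calls_ancestor}
    evo = {c.key: c for c in calls_evolved}
    contigs_a = {c.contig for c in calls_ancestor}
    contigs_e = {c.contig for c in calls_evolved}
    if contigs_a and contigs_e and not (contigs_a & contigs_e):
        warnings.warn(
            "ancestor and evolved call sets share no reference names; "
            "check that both were called against the same reference",
            stacklevel=2,
        )

    rows = []
    for key in anc.keys() | evo.keys():
        a, e = anc.get(key), evo.get(key)
        fa = a.alt_frequency if a is not None else 0.0
        fe = e.alt_frequency if e is not None else 0.0
        da = a.depth if a is not None else (e.depth if e is not None else 0)
        de = e.depth if e is not None else (a.depth if a is not None else 0)
        if abs(fe - fa) < min_freq_diff:
            continue
        if cov_mode == "both":
            covered = da >= min_cov and de >= min_cov
        else:
            carrier_depths = [c.depth for c in (a, e) if c is not None]
            covered = all(d >= min_cov for d in carrier_depths)
        if not covered:
            continue
        contig, pos, ref, alt = key
        rows.append(
            {
                "contig": contig,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "freq_ancestor": fa,
                "freq_evolved": fe,
                "depth": min(da, de),
                "direction": GAINED if fe > fa else LOST,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "contig",
            "pos",
            "ref",
            "alt",
            "freq_ancestor",
            "freq_evolved",
            "depth",
            "direction",
        ],
    )
    return df.sort_values(["contig", "pos", "ref", "alt"]).reset_index(drop=True)


def intermediate_frequency_report(
    calls: list[VariantCall],
    low: float = 0.2,
    high: float = 0.8,
) -> pd.DataFrame:
    """Calls at intermediate frequency — the heterokaryon signature.

    Samples that are mixtures of two nuclear genotypes carry variants at
    frequencies between ``low`` and ``high`` (exclusive); the strict
    pairwise filter drops these, so they are reported separately rather
    than by relaxing thresholds.
    """
    rows = [
        dataclasses.asdict(c) for c in calls if low < c.alt_frequency < high
    ]
    return pd.DataFrame(
        rows, columns=["contig", "pos", "ref", "alt", "depth", "alt_frequency"]
    )
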