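"""Allele-frequency reports, ddPCR genotyping, clone cohorts, kinetics.

Covers Poisson-corrected droplet digital PCR copy-number calls, the
three-assay clonal genotype decision table (short-read NGS + gel shift +
ddPCR), cohort summaries, deletion-adjusted bulk allele frequencies, and
time-to-half-plateau (T50) estimation for modification time courses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .variants import ClassificationConfig, VariantCall, cluster_ld_patterns

MODIFIED_CATEGORIES = (
    "small_indel",
    "intermediate_deletion",
    "large_deletion",
    "large_insertion",
    "insertion_with_deletion",
)


@dataclass
class AlleleFrequencyReport:
    fractions: dict[str, float]  # over valid calls
    n_valid: int
    n_invalid: int
    unique_patterns: dict[str, int]
    diversity_fold: float | None  # total unique patterns / unique small INDELs


@dataclass
class DdpcrResult:
    target_total: int
    target_negative: int
    reference_total: int
    reference_negative: int
    lambda_target: float
    lambda_reference: float
    copy_ratio: float
    intact_copies: int


@dataclass
class CloneGenotype:
    allele1: str
    allele2: str
    resolved: bool = True
    note: str = ""
    evidence: dict = field(default_factory=dict)

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele1, self.allele2)

    def n_ld(self) -> int:
        return sum(a == "LD" for a in self.alleles)


@dataclass
class KineticsFit:
    times: list[float]
    rates: list[float]
    plateau: float
    t50: float | None
    reason: str = ""


def _event_signature(call: VariantCall) -> tuple:
    sig = []
    for e in call.events:
        if hasattr(e, "ref_end"):
            sig.append(("D", e.ref_start, e.ref_end, e.junction_insertion))
        else:
            sig.append(("I", e.ref_pos, e.inserted_sequence))
    return tuple(sig)


def allele_frequency_report(
    calls: list[VariantCall], cfg: ClassificationConfig | None = None
) -> AlleleFrequencyReport:
    """Category fractions over valid calls, plus unique-pattern counts.

    Large deletions are de-duplicated via tolerance clustering; other
    modified categories by exact event signature. The diversity fold is
    the total number of unique modification patterns over the number of
    unique small-INDEL patterns (None when no small INDEL exists).
    """
    cfg = cfg or ClassificationConfig()
    valid = [c for c in calls if c.category != "invalid"]
    n_invalid = len(calls) - len(valid)
    if not valid:
        raise ValueError("no valid calls")
    fractions = {
        cat: sum(c.category == cat for c in valid) / len(valid)
        for cat in ("unmodified",) + MODIFIED_CATEGORIES
    }
    unique: dict[str, int] = {}
    ld_calls = [c for c in valid if c.category == "large_deletion"]
    unique["large_deletion"] = len(cluster_ld_patterns(ld_calls, cfg)) if ld_calls else 0
    for cat in MODIFIED_CATEGORIES:
        if cat == "large_deletion":
            continue
        unique[cat] = len({_event_signature(c) for c in valid if c.category == cat})
    total_unique = sum(unique.values())
    fold = total_unique / unique["small_indel"] if unique["small_indel"] else None
    return AlleleFrequencyReport(fractions, len(valid), n_invalid, unique, fold)


def ddpcr_genotype(
    target_total: int,
    target_negative: int,
    reference_total: int,
    reference_negative: int,
    thresholds: tuple[float, float] = (0.25, 0.75),
) -> DdpcrResult:
    """Poisson-corrected drop-off copy-number call.

    lambda = -ln(negatives/total) per channel; the target/reference
    concentration ratio maps to 0, 1 or 2 intact target copies via the
    two thresholds.
    """
    for total, neg, chan in (
        (target_total, target_negative, "target"),
        (reference_total, reference_negative, "reference"),
    ):
        if total <= 0:
            raise ValueError(f"{chan} channel has no droplets")
        if not 0 <= neg <= total:
            raise ValueError(f"{chan} negatives outside [0, total]")
        if neg == 0:
            raise ValueError(f"{chan} channel saturated (no negative droplets)")
    lam_t = -math.log(target_negative / target_total)
    lam_r = -math.log(reference_negative / reference_total)
    if lam_r == 0:
        raise ValueError("reference channel shows no template")
    ratio = lam_t / lam_r
    lo, hi = thresholds
    intact = 2 if ratio >= hi else (1 if ratio >= lo else 0)
    return DdpcrResult(
        target_total,
        target_negative,
        reference_total,
        reference_negative,
        lam_t,
        lam_r,
        ratio,
        intact,
    )


def combine_clone_genotype(
    sr_ngs,
    gel_shift: bool | None,
    intact_copies: int,
) -> CloneGenotype:
    """Three-assay clonal genotype decision table.

    ``sr_ngs`` is either the string ``"failure"`` (no short-read PCR
    product) or a pair of allele labels such as ``("SI:-9", "SI:-9")``;
    identical labels mean a homozygous short-read call. Labels use a
    ``CLASS[:detail]`` form with CLASS in {WT, SI, HDR, HBD}.
    ``intact_copies`` comes from the ddPCR drop-off assay. Inconsistent
    evidence is flagged unresolved, never silently dropped.
    """
    ev = {"sr_ngs": sr_ngs, "gel_shift": gel_shift, "intact_copies": intact_copies}
    if intact_copies not in (0, 1, 2):
        raise ValueError("intact_copies must be 0, 1 or 2")

    def unresolved(note: str) -> CloneGenotype:
        return CloneGenotype("?", "?", resolved=False, note=note, evidence=ev)

    if sr_ngs == "failure" or sr_ngs is None:
        if intact_copies == 0:
            return CloneGenotype("LD", "LD", evidence=ev)
        return unresolved("short-read failure but intact copies remain")
    a1, a2 = sr_ngs
    if a1 == a2:  # homozygous short-read call
        if intact_copies == 2:
            geno = CloneGenotype(a1, a2, evidence=ev)
        elif intact_copies == 1:
            geno = CloneGenotype(a1, "LD", evidence=ev)
        else:
            return unresolved("homozygous short-read call with zero intact copies")
    else:  # heterozygous
        if intact_copies == 2:
            geno = CloneGenotype(a1, a2, evidence=ev)
        else:
            return unresolved("heterozygous short-read call with missing copies")
    if gel_shift is True and geno.n_ld() == 0:
        return unresolved("gel shift indicates a large deletion the calls lack")
    return geno


def summarize_clone_cohort(genotypes, weights=None, frameshift=None) -> dict:
    """Cohort summary over clone genotypes.

    ``genotypes`` may be CloneGenotype objects or (allele1, allele2)
    pairs; ``weights`` allows fractional cohorts (e.g. genotype-class
    percentages). ``frameshift``, when given, maps each clone to a pair
    of booleans marking frameshift small INDELs for total-KO counting
    (LD alleles always count as knocked out).
    """
    pairs = []
    for g in genotypes:
        pairs.append(g.alleles if isinstance(g, CloneGenotype) else tuple(g))
    if not pairs:
        raise ValueError("empty cohort")
    w = np.ones(len(pairs)) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != len(pairs):
        raise ValueError("weights length mismatch")
    total_clones = w.sum()
    ld_alleles = sum(
        wi * sum(a == "LD" for a in p) for wi, p in zip(w, pairs)
    )
    clones_with_ld = sum(wi for wi, p in zip(w, pairs) if "LD" in p)
    out = {
        "n_clones": float(total_clones),
        "ld_allele_freq_pct": 100.0 * ld_alleles / (2 * total_clones),
        "clones_with_ld_pct": 100.0 * clones_with_ld / total_clones,
    }
    if frameshift is not None:
        ko = 0.0
        for wi, p, fs in zip(w, pairs, frameshift):
            knocked = all(
                a == "LD" or (a.startswith("SI") and f) for a, f in zip(p, fs)
            )
            ko += wi * knocked
        out["total_ko_pct"] = 100.0 * ko / total_clones
    return out


def ld_adjusted_frequency(sr_fraction_pct: float, intact_fraction: float) -> dict:
    """Scale a short-read allele percentage by the intact-allele fraction."""
    if not 0 <= sr_fraction_pct <= 100:
        raise ValueError("sr_fraction_pct must be a percentage")
    if not 0 <= intact_fraction <= 1:
        raise ValueError("intact_fraction must be a proportion")
    return {
        "adjusted_pct": sr_fraction_pct * intact_fraction,
        "ld_attributed_pct": (1 - intact_fraction) * 100.0,
    }


def estimate_t50(times, rates) -> KineticsFit:
    """Time to half of the maximum observed modification rate.

    The plateau is the series maximum; T50 is the linearly interpolated
    first crossing of plateau/2 (first-crossing semantics tolerate
    non-monotone wobble).
    """
    times = [float(t) for t in times]
    rates = [float(r) for r in rates]
    if len(times) < 3 or len(times) != len(rates):
        raise ValueError("need at least 3 matched time points")
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("times must be strictly increasing")
    plateau = max(rates)
    if plateau <= 0:
        return KineticsFit(times, rates, plateau, None, reason="no modification signal")
    half = plateau / 2
    if rates[0] >= half:
        return KineticsFit(times, rates, plateau, times[0])
    for i in range(1, len(rates)):
        if rates[i] >= half:
            t0, t1 = times[i - 1], times[i]
            r0, r1 = rates[i - 1], rates[i]
            t50 = t0 + (half - r0) * (t1 - t0) / (r1 - r0)
            return KineticsFit(times, rates, plateau, t50)
    return KineticsFit(times, rates, plateau, None, reason="half-plateau never reached")
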