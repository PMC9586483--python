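"""Synthetic data generation.

Builds the 9-template deletion standard (one wild-type amplicon plus eight
templates carrying centered artificial deletions, each tagged with a 6-bp
barcode), edited-cell allele pools, and sequencing reads for both the
UMI-tagged long-read workflow and the paired-end long-amplicon workflow,
complete with PCR duplication bias, chimeras, substitution errors, and
per-read truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import BASES, random_from_pattern, revcomp
from .align import apply_events
from .reference import AmpliconReference
from .umi import DEFAULT_UMI_PATTERN, UmiSpec

DEFAULT_DELETION_SIZES = (4416, 3872, 3408, 3079, 2415, 1926, 1408, 921)
DEFAULT_BARCODES = (
    "AACGTG",
    "CGTACA",
    "GTAGCC",
    "TCCAGT",
    "ACTGGA",
    "CAGTTC",
    "GGATAC",
    "TTGCAG",
    "ATCCGT",
)
DEFAULT_PRIMER5 = "CAGGTTCACGTAGCTGACCA"
DEFAULT_PRIMER3 = "TGGACGATCCTGAACGTCAG"


@dataclass
class StandardDesign:
    """Design of the synthetic large-deletion standard."""

    wt_length: int = 5490
    deletion_sizes: tuple[int, ...] = DEFAULT_DELETION_SIZES
    template_barcodes: tuple[str, ...] = DEFAULT_BARCODES
    fractions: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.deletion_sizes) + 1
        if not self.fractions:
            # WT carries 80%, the deleted templates split 20% evenly
            if self.deletion_sizes:
                share = 0.2 / len(self.deletion_sizes)
                self.fractions = tuple([share] * len(self.deletion_sizes) + [0.8])
            else:
                self.fractions = (1.0,)
        if len(self.fractions) != n:
            raise ValueError("need one fraction per template (deletions + WT)")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if len(self.template_barcodes) < n:
            raise ValueError("need one barcode per template")
        bcs = self.template_barcodes[:n]
        if len(set(bcs)) != len(bcs):
            raise ValueError("template barcodes must be unique")
        if any(len(b) != 6 for b in bcs):
            raise ValueError("template barcodes must be 6 bases long")
        for i, size in enumerate(self.deletion_sizes, start=1):
            if size >= self.wt_length:
                raise ValueError(
                    f"template {i}: deletion of {size} bp does not fit in "
                    f"a {self.wt_length} bp amplicon"
                )

    @property
    def n_templates(self) -> int:
        return len(self.deletion_sizes) + 1


@dataclass
class SimConfig:
    """Knobs for library simulation."""

    seed: int = 0
    n_molecules: int = 1000
    mean_duplicates: float = 35.0
    length_bias: float = 0.3  # beta in exp(-beta * length / 1000)
    chimera_rate: float = 0.0
    error_rate: float = 0.0
    umi_spec: UmiSpec = field(
        default_factory=lambda: UmiSpec(DEFAULT_PRIMER5, DEFAULT_PRIMER3, DEFAULT_UMI_PATTERN)
    )

    def __post_init__(self) -> None:
        if self.n_molecules <= 0:
            raise ValueError("n_molecules must be positive")
        if not 0 <= self.chimera_rate < 1:
            raise ValueError("chimera_rate must be in [0, 1)")
        if not 0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")


@dataclass
class FastqRecord:
    read_id: str
    sequence: str
    quality: str = ""

    def __post_init__(self) -> None:
        if not self.quality:
            self.quality = "I" * len(self.sequence)


@dataclass
class AlleleSpec:
    """One designed allele of an edited-cell pool."""

    name: str
    category: str
    events: list = field(default_factory=list)
    fraction: float = 0.0

    CATEGORIES = (
        "unmodified",
        "small_indel",
        "intermediate_deletion",
        "large_deletion",
        "large_insertion",
        "insertion_with_deletion",
    )

    def __post_init__(self) -> None:
        if self.category not in self.CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def build_standard(design: StandardDesign, seed: int = 0):
    """Construct the 9-template standard.

    Returns (templates, reference, truth) where templates is a list of
    (name, sequence), the deleted block of template i is centered on the
    reference cut site, and every template starts with its 6-bp barcode
    (excluded from deletion-size accounting).
    """
    rng = np.random.default_rng(seed)
    body = random_sequence(design.wt_length, rng)
    cut = design.wt_length // 2
    ref = AmpliconReference("standard_wt", body, cut_site=cut)
    templates = []
    rows = []
    n_del = len(design.deletion_sizes)
    for i, size in enumerate(design.deletion_sizes, start=1):
        start = cut - size // 2
        end = start + size
        if start < 1 or end > design.wt_length - 1:
            raise ValueError(
                f"template {i}: centered deletion of {size} bp exceeds the amplicon"
            )
        seq = design.template_barcodes[i - 1] + body[:start] + body[end:]
        name = f"template_{i}"
        templates.append((name, seq))
        rows.append(
            {
                "template": name,
                "deletion_size": size,
                "del_start": start,
                "del_end": end,
                "barcode": design.template_barcodes[i - 1],
                "fraction": design.fractions[i - 1],
            }
        )
    wt_name = f"template_{n_del + 1}"
    templates.append((wt_name, design.template_barcodes[n_del] + body))
    rows.append(
        {
            "template": wt_name,
            "deletion_size": 0,
            "del_start": -1,
            "del_end": -1,
            "barcode": design.template_barcodes[n_del],
            "fraction": design.fractions[n_del],
        }
    )
    return templates, ref, pd.DataFrame(rows)


def build_allele_pool(ref: AmpliconReference, specs: list[AlleleSpec]):
    """Materialize allele sequences from event lists against a reference."""
    total = sum(s.fraction for s in specs)
    if abs(total - 1.0) > 1e-9:
        raise ValueError("allele fractions must sum to 1")
    return [(s.name, apply_events(ref.sequence, s.events)) for s in specs]


def _apply_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for pos in positions:
        options = [b for b in BASES if b != chars[pos]]
        chars[pos] = options[rng.integers(3)]
    return "".join(chars)


def _shared_kmer_junction(a: str, b: str, rng: np.random.Generator, k: int = 15):
    """Pick a chimera junction inside a shared k-mer, else uniform."""
    kmers = {}
    for i in range(0, len(a) - k + 1, 4):
        kmers.setdefault(a[i : i + k], i)
    hits = []
    for j in range(0, len(b) - k + 1, 4):
        i = kmers.get(b[j : j + k])
        if i is not None:
            hits.append((i, j))
    if hits:
        i, j = hits[rng.integers(len(hits))]
        off = int(rng.integers(k + 1))
        return i + off, j + off
    return int(rng.integers(len(a))), int(rng.integers(len(b)))


def simulate_umi_library(templates, fractions, config: SimConfig):
    """Simulate a dual-UMI tagged long-read library.

    Each parent molecule is drawn by ``fractions``, tagged with a fresh
    UMI pair, then amplified with a length-biased duplicate count
    (``1 + Poisson(mean_duplicates * exp(-beta * L / 1000))``). A
    ``chimera_rate`` fraction of reads is replaced by splices of two parent
    molecules (joined inside a shared 15-mer when one exists), inheriting
    mismatched UMI ends. Substitution errors are applied last.

    Returns (records, truth) with one truth row per emitted read.
    """
    fractions = np.asarray(fractions, dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(config.seed)
    spec = config.umi_spec
    names = [t[0] for t in templates]
    seqs = [t[1].upper() for t in templates]

    parent_idx = rng.choice(len(templates), size=config.n_molecules, p=fractions)
    molecules = []
    for m, ti in enumerate(parent_idx):
        umi5 = random_from_pattern(spec.pattern, rng)
        umi3 = random_from_pattern(spec.pattern, rng)
        molecules.append((m, int(ti), umi5, umi3))

    lengths = np.array([len(seqs[ti]) for _, ti, _, _ in molecules])
    lam = config.mean_duplicates * np.exp(-config.length_bias * lengths / 1000.0)
    n_reads = 1 + rng.poisson(lam)

    def tagged_seq(mol):
        _, ti, umi5, umi3 = mol
        return spec.primer5 + umi5 + seqs[ti] + revcomp(umi3) + revcomp(spec.primer3)

    records: list[FastqRecord] = []
    rows = []
    for mol, count in zip(molecules, n_reads):
        m, ti, umi5, umi3 = mol
        base = tagged_seq(mol)
        for j in range(count):
            rid = f"mol{m}_r{j}"
            seq = base
            is_chimera = False
            c_umi3 = umi3
            if config.chimera_rate > 0 and rng.random() < config.chimera_rate and len(molecules) > 1:
                other = molecules[int(rng.integers(len(molecules)))]
                if other[0] != m:
                    ja, jb = _shared_kmer_junction(seqs[ti], seqs[other[1]], rng)
                    insert = seqs[ti][:ja] + seqs[other[1]][jb:]
                    seq = (
                        spec.primer5
                        + umi5
                        + insert
                        + revcomp(other[3])
                        + revcomp(spec.primer3)
                    )
                    is_chimera = True
                    c_umi3 = other[3]
            seq = _apply_errors(seq, rng, config.error_rate)
            records.append(FastqRecord(rid, seq))
            rows.append(
                {
                    "read_id": rid,
                    "molecule": m,
                    "template": names[ti],
                    "is_duplicate": j > 0,
                    "is_chimera": is_chimera,
                    "umi5": umi5,
                    "umi3": c_umi3,
                }
            )
    return records, pd.DataFrame(rows)


def simulate_longamp_reads(
    pool,
    fractions,
    n_fragments: int,
    read_length: int = 250,
    fragment_mean: float = 450.0,
    fragment_sd: float = 80.0,
    seed: int = 0,
    error_rate: float = 0.0,
    mass_weighted: bool = True,
):
    """Simulate paired-end reads from fragmented long amplicons.

    Fragment start positions are uniform along each parent amplicon;
    fragment counts per allele are proportional to fraction x length when
    ``mass_weighted`` (tagmentation samples mass, not molecules). Returns
    (r1_records, r2_records, truth).
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    fractions = np.asarray(fractions, dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    names = [p[0] for p in pool]
    seqs = [p[1].upper() for p in pool]
    weights = fractions * (np.array([len(s) for s in seqs]) if mass_weighted else 1.0)
    weights = weights / weights.sum()
    counts = rng.multinomial(n_fragments, weights)
    r1s, r2s, rows = [], [], []
    pair = 0
    for ai, n in enumerate(counts):
        L = len(seqs[ai])
        for _ in range(n):
            flen = int(np.clip(rng.normal(fragment_mean, fragment_sd), 50, min(L, 590)))
            start = int(rng.integers(0, L - flen + 1))
            frag = seqs[ai][start : start + flen]
            r1 = frag[:read_length]
            r2 = revcomp(frag)[:read_length]
            rid = f"frag{pair}"
            r1s.append(FastqRecord(rid, _apply_errors(r1, rng, error_rate)))
            r2s.append(FastqRecord(rid, _apply_errors(r2, rng, error_rate)))
            rows.append(
                {
                    "read_id": rid,
                    "allele": names[ai],
                    "frag_start": start,
                    "frag_len": flen,
                }
            )
            pair += 1
    return r1s, r2s, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plain-text I/O


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_fastq(records: list[FastqRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.quality}\n")


def read_fastq(path) -> list[FastqRecord]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(FastqRecord(rec.id, str(rec.seq), quals))
    return out


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
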