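"""Synthetic data: clade-structured LTR genomes and methylation matrices.

Everything the pipeline consumes can be generated at desk scale: a toy
genome carrying planted full-length (paired-LTR) and solo LTR copies whose
per-clade divergence from a generated consensus mirrors a young, recently
amplified retroviral family (defaults 1.8% / 9.1% / 12.9%), the matching
RepeatMasker-style annotation table, and mice x loci percent-methylation
matrices with clade-dependent locus means, per-locus noise, gel intensities
and below-LOD dropouts.

Clade structure is created by a founder-then-member scheme: each clade's
founder accumulates half the clade's divergence from the consensus, and
members diverge independently from the founder by the other half.  The
shared founder substitutions are genuine synapomorphies, which is what lets
a neighbor-joining tree recover the clades (independent star-shaped noise
around the consensus would not).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quant import LaneQuant, MethylationTable
from .repeats import RepeatAnnotation, revcomp, write_repeatmasker_out

__all__ = [
    "CladeSpec",
    "SimConfig",
    "GroundTruth",
    "make_consensus",
    "plant_elements",
    "default_locus_map",
    "simulate_methylation",
    "simulate_gel",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class CladeSpec:
    name: str
    n_elements: int
    divergence: float          # expected per-site substitution rate vs consensus
    mean_methylation: float    # clade-level mean of locus means (%)


@dataclass
class SimConfig:
    """Study-condition defaults for the synthetic generators.

    The clade roster mirrors the structure of the IAPLTR1_Mm family: a large
    conserved clade (1.8% divergence, most methylated) and two smaller
    diverged clades (9.1% and 12.9%), with clade-level mean methylation of
    79 / 70 / 68 percent.  17 mice and 7 loci per clade reproduce the shape
    of a 17 x 21 CoBRA panel.
    """

    seed: int = 17
    genome_length: int = 1_200_000
    consensus_length: int = 337
    clades: tuple[CladeSpec, ...] = (
        CladeSpec("black", 40, 0.018, 79.0),
        CladeSpec("red", 15, 0.091, 70.0),
        CladeSpec("green", 12, 0.129, 68.0),
    )
    paired_fraction: float = 0.5
    body_length_range: tuple[int, int] = (5000, 7000)
    min_spacing: int = 8500          # background between insertions; kept above
                                     # the LTR pairing gap window so paired/solo
                                     # structure is unambiguous
    subtype: str = "IAPLTR1_Mm"
    n_mice: int = 17
    n_males: int = 7
    loci_per_clade: int = 7
    locus_mean_sd: float = 7.0       # sd of locus means around the clade mean (%)
    within_locus_sd_range: tuple[float, float] = (2.0, 8.0)
    lod_dropout_prob: float = 0.02
    gel_noise_cv: float = 0.05
    gel_base_intensity: float = 1000.0
    lod_intensity: float = 50.0

    def __post_init__(self) -> None:
        if not 0 <= self.paired_fraction <= 1:
            raise ValueError("paired_fraction must be in [0, 1]")
        if not 0 <= self.lod_dropout_prob <= 1:
            raise ValueError("lod_dropout_prob must be in [0, 1]")
        if any(c.n_elements < 0 for c in self.clades):
            raise ValueError("clade sizes must be >= 0")


@dataclass
class PlantedElement:
    id: str
    chrom: str
    start: int      # 0-based half-open
    end: int
    strand: str
    structure: str  # solo_ltr / five_prime_of_pair / three_prime_of_pair
    clade: str
    divergence: float  # realised p-distance to consensus


@dataclass
class GroundTruth:
    elements: list[PlantedElement] = field(default_factory=list)
    clade_of: dict[str, str] = field(default_factory=dict)
    locus_means: dict[str, float] = field(default_factory=dict)
    locus_sds: dict[str, float] = field(default_factory=dict)
    masked_cells: set[tuple[str, str]] = field(default_factory=set)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def make_consensus(config: SimConfig | None = None,
                   rng: np.random.Generator | None = None) -> str:
    """Random LTR-like consensus with guaranteed CpG content.

    Contains at least one ``ACGGCG`` motif on each strand (the antisense
    copy, ``CGCCGT`` on the written strand, is what makes a CoBRA assay on
    the antisense strand designable) and at least 2 CpGs per 100 nt; fully
    determined by the config seed.
    """
    cfg = config or SimConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    L = cfg.consensus_length
    need_cpg = max(1, (2 * L) // 100)
    while True:
        seq = list(_random_seq(rng, L))
        pos = int(rng.integers(130, L - 60))
        seq[pos:pos + 6] = "ACGGCG"
        # antisense-strand recognition site near the element 5' end, far
        # enough in for an element-internal primer upstream of it
        pos2 = int(rng.integers(40, 110))
        seq[pos2:pos2 + 6] = "CGCCGT"
        # sprinkle CpGs until dense enough
        s = "".join(seq)
        cpg = s.count("CG")
        attempts = 0
        while cpg < need_cpg and attempts < 10 * L:
            p = int(rng.integers(0, L - 1))
            if s[p:p + 2] != "CG":
                seq[p], seq[p + 1] = "C", "G"
                s = "".join(seq)
                cpg = s.count("CG")
            attempts += 1
        if "ACGGCG" in s and s.count("CG") >= need_cpg:
            return s


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-site substitution with probability ``rate`` to a different base."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = BASES[BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _p_dist(a: str, b: str) -> float:
    return sum(x != y for x, y in zip(a, b)) / len(a)


def plant_elements(
    config: SimConfig | None = None,
    consensus: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], str, GroundTruth]:
    """Build a genome with planted clade-structured LTR insertions.

    Returns ``(genome, rmout_text, truth)``: a single-chromosome genome
    dict, the matching RepeatMasker-style annotation text (strand written as
    ``+``/``C``, per-copy divergence as percent), and the planted ground
    truth.  Paired insertions carry two identical LTR copies around a random
    body; each insertion sits in unique random background with at least
    ``min_spacing`` nt to its neighbours.
    """
    cfg = config or SimConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    consensus = consensus or make_consensus(cfg, rng)
    L = len(consensus)

    # per-element LTR sequences, clade labels, paired flags
    members: list[tuple[str, str, bool]] = []  # (clade, seq, paired)
    for clade in cfg.clades:
        founder = _mutate(consensus, clade.divergence / 2.0, rng)
        for _ in range(clade.n_elements):
            seq = _mutate(founder, clade.divergence / 2.0, rng)
            paired = bool(rng.random() < cfg.paired_fraction)
            members.append((clade.name, seq, paired))
    order = rng.permutation(len(members))
    members = [members[i] for i in order]

    insert_lens = []
    bodies = []
    for _, seq, paired in members:
        if paired:
            body = _random_seq(rng, int(rng.integers(*cfg.body_length_range)))
            bodies.append(body)
            insert_lens.append(2 * L + len(body))
        else:
            bodies.append("")
            insert_lens.append(L)
    total_insert = sum(insert_lens)
    n = len(members)
    bg_total = cfg.genome_length - total_insert
    if bg_total < (n + 1) * cfg.min_spacing:
        raise ValueError("genome_length too small for requested insertions")
    # background segment lengths: min_spacing each plus a random split of the rest
    extra = bg_total - (n + 1) * cfg.min_spacing
    cutpoints = np.sort(rng.integers(0, extra + 1, size=n))
    seg_extra = np.diff(np.concatenate([[0], cutpoints, [extra]]))
    seg_lens = seg_extra + cfg.min_spacing

    chrom = "chr1"
    parts: list[str] = []
    truth = GroundTruth()
    annotations: list[RepeatAnnotation] = []
    pos = 0
    eid = 0
    for i, (clade, seq, paired) in enumerate(members):
        parts.append(_random_seq(rng, int(seg_lens[i])))
        pos += int(seg_lens[i])
        strand = "+" if rng.random() < 0.5 else "-"
        div = _p_dist(seq, consensus)
        if paired:
            body = bodies[i]
            insertion = seq + body + seq
            genomic = insertion if strand == "+" else revcomp(insertion)
            parts.append(genomic)
            # genomic coordinates of the two LTR copies
            left = (pos, pos + L)
            right = (pos + L + len(body), pos + 2 * L + len(body))
            if strand == "+":
                five, three = left, right
            else:
                five, three = right, left
            for (s0, s1), structure in ((five, "five_prime_of_pair"),
                                        (three, "three_prime_of_pair")):
                eid += 1
                pid = f"IAP{eid}"
                truth.elements.append(PlantedElement(
                    pid, chrom, s0, s1, strand, structure, clade, div))
                truth.clade_of[pid] = clade
                annotations.append(RepeatAnnotation(
                    chrom, s0 + 1, s1, strand, cfg.subtype, "LTR/ERVK",
                    round(100 * div, 1), score=int(L * (1 - div))))
            pos += len(insertion)
        else:
            genomic = seq if strand == "+" else revcomp(seq)
            parts.append(genomic)
            eid += 1
            pid = f"IAP{eid}"
            truth.elements.append(PlantedElement(
                pid, chrom, pos, pos + L, strand, "solo_ltr", clade, div))
            truth.clade_of[pid] = clade
            annotations.append(RepeatAnnotation(
                chrom, pos + 1, pos + L, strand, cfg.subtype, "LTR/ERVK",
                round(100 * div, 1), score=int(L * (1 - div))))
            pos += L
    parts.append(_random_seq(rng, int(seg_lens[n])))
    genome = {chrom: "".join(parts)}
    assert len(genome[chrom]) == cfg.genome_length
    annotations.sort(key=lambda a: (a.chrom, a.start))
    truth.elements.sort(key=lambda e: (e.chrom, e.start))
    return genome, write_repeatmasker_out(annotations), truth


def default_locus_map(config: SimConfig | None = None) -> dict[str, str]:
    """A locus -> clade roster of ``loci_per_clade`` loci per clade."""
    cfg = config or SimConfig()
    out = {}
    for clade in cfg.clades:
        for i in range(1, cfg.loci_per_clade + 1):
            out[f"{clade.name}_L{i}"] = clade.name
    return out


def simulate_methylation(
    config: SimConfig | None = None,
    clade_labels: Mapping[str, str] | None = None,
    y_linked_loci: Sequence[str] = (),
    rng: np.random.Generator | None = None,
) -> tuple[MethylationTable, GroundTruth]:
    """Draw a mice x loci percent-methylation matrix with clade structure.

    Per locus, the true mean is Normal(clade mean, ``locus_mean_sd``)
    truncated to [0, 100]; per mouse, the observed value is Normal(true
    mean, sigma_locus) with sigma_locus uniform in
    ``within_locus_sd_range``, truncated to [0, 100].  Cells drop out
    independently with ``lod_dropout_prob`` (masked "lod"); Y-linked loci
    are masked "absent" for female mice (the first ``n_males`` mice are
    male).
    """
    cfg = config or SimConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    clade_labels = dict(clade_labels) if clade_labels else default_locus_map(cfg)
    clade_mean = {c.name: c.mean_methylation for c in cfg.clades}
    mice = [f"Mouse{i}" for i in range(1, cfg.n_mice + 1)]
    males = set(mice[:cfg.n_males])
    truth = GroundTruth()
    values = pd.DataFrame(index=mice, columns=list(clade_labels), dtype=float)
    reason = pd.DataFrame("", index=mice, columns=list(clade_labels))
    for locus, clade in clade_labels.items():
        if clade not in clade_mean:
            raise ValueError(f"unknown clade {clade!r} for locus {locus!r}")
        m_star = float(np.clip(rng.normal(clade_mean[clade], cfg.locus_mean_sd),
                               0.0, 100.0))
        sigma = float(rng.uniform(*cfg.within_locus_sd_range))
        truth.locus_means[locus] = m_star
        truth.locus_sds[locus] = sigma
        draws = np.clip(rng.normal(m_star, sigma, size=cfg.n_mice), 0.0, 100.0)
        for mouse, v in zip(mice, draws):
            if locus in y_linked_loci and mouse not in males:
                values.at[mouse, locus] = np.nan
                reason.at[mouse, locus] = "absent"
                truth.masked_cells.add((mouse, locus))
            elif rng.random() < cfg.lod_dropout_prob:
                values.at[mouse, locus] = np.nan
                reason.at[mouse, locus] = "lod"
                truth.masked_cells.add((mouse, locus))
            else:
                values.at[mouse, locus] = v
    table = MethylationTable(values, reason, clade_labels)
    return table, truth


def simulate_gel(
    table: MethylationTable,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[LaneQuant]:
    """Inverse model: emit noisy band intensities for each table cell.

    Per present cell M: I_cut = c * M * eps1, I_uncut = c * (100 - M) * eps2
    with lognormal multiplicative noise of coefficient of variation
    ``gel_noise_cv`` and a random per-lane scale c.  Cells masked "lod" emit
    a lane whose uncut band sits below ``lod_intensity``; cells masked
    "absent" emit nothing.  Each locus gets a 0% and a high-methylation
    control lane (mouse ids ``control_0`` / ``control_high``).
    """
    cfg = config or SimConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    cv = cfg.gel_noise_cv
    sigma = np.sqrt(np.log1p(cv ** 2)) if cv > 0 else 0.0

    def eps() -> float:
        if sigma == 0.0:
            return 1.0
        return float(rng.lognormal(-sigma ** 2 / 2.0, sigma))

    base = cfg.gel_base_intensity / 100.0
    lanes: list[LaneQuant] = []
    for locus in table.loci:
        for mouse in table.mice:
            m = table.values.at[mouse, locus]
            why = table.mask_reason.at[mouse, locus]
            if np.isnan(m):
                if why == "lod":
                    uncut = float(rng.uniform(0.05, 0.8)) * cfg.lod_intensity
                    cut = uncut * float(rng.uniform(2.0, 8.0))
                    lanes.append(LaneQuant(mouse, locus, uncut, cut))
                continue
            c = base * float(rng.uniform(0.8, 1.2))
            lanes.append(LaneQuant(
                mouse, locus, c * (100.0 - m) * eps(), c * m * eps()))
        c = base * float(rng.uniform(0.8, 1.2))
        lanes.append(LaneQuant("control_0", locus,
                               c * 99.0 * eps(), c * 1.0 * eps(), flag="control"))
        lanes.append(LaneQuant("control_high", locus,
                               c * 4.0 * eps(), c * 96.0 * eps(), flag="control"))
    return lanes
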