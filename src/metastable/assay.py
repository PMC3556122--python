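"""CoBRA assay design: bisulfite conversion, site detection, primers, digest.

Combined bisulfite restriction analysis (CoBRA) reads methylation at
specific CpGs from gel bands: bisulfite treatment converts unmethylated
cytosines to thymine (after PCR) while 5-methylcytosines survive, so a
restriction site whose recognition string contains CpG cytosines exists in
the PCR product only if those CpGs were methylated in the genomic template.
The enzyme used here recognises ``ACGGCG``, which carries two CpGs; loss of
methylation at either destroys the site, so cut vs uncut band intensity
reports joint methylation of the pair.

Assays are designed on the bisulfite-converted antisense strand of the
element's 5' end plus its unique genomic flank: the forward primer sits
fully inside the element (locus-homologous), the reverse primer fully inside
the unique flank (locus-specific), and the amplicon spans the junction and
at least one methylation-dependent site.  CpG cytosines inside a primer are
degenerate (Y on the template sense, R after reverse complement) so priming
is unbiased by methylation state.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .repeats import FIVE_PRIME, LtrElement, RepeatAnnotation, revcomp

__all__ = [
    "MethylationState",
    "RestrictionSite",
    "CobraAssay",
    "AssayConfig",
    "AssayDesignError",
    "bisulfite_convert",
    "find_methylation_dependent_sites",
    "select_candidates",
    "design_primers",
    "in_silico_digest",
    "verify_assay",
]


class AssayDesignError(ValueError):
    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class MethylationState:
    """Methylation marks on CpG cytosines of one strand.

    Maps 0-based positions of CpG cytosines to True (methylated) / False.
    Positions are validated against the sequence at conversion time: marking
    a non-CpG cytosine is an error, since bisulfite chemistry converts those
    unconditionally.
    """

    def __init__(self, marks: Mapping[int, bool] | Iterable[int] | None = None):
        if marks is None:
            self.marks: dict[int, bool] = {}
        elif isinstance(marks, Mapping):
            self.marks = dict(marks)
        else:
            self.marks = {int(p): True for p in marks}

    @classmethod
    def unmethylated(cls) -> "MethylationState":
        return cls()

    @classmethod
    def fully_methylated(cls, sequence: str) -> "MethylationState":
        seq = sequence.upper()
        return cls({m.start(): True for m in re.finditer("(?=CG)", seq)})

    def methylated_positions(self) -> set[int]:
        return {p for p, v in self.marks.items() if v}

    def validate(self, sequence: str) -> None:
        seq = sequence.upper()
        for p in self.marks:
            if not (0 <= p < len(seq) - 1 and seq[p] == "C" and seq[p + 1] == "G"):
                raise ValueError(f"position {p} is not a CpG cytosine")


def bisulfite_convert(sequence: str, state: MethylationState | None = None) -> str:
    """In-silico bisulfite conversion of one strand.

    Every C becomes T except CpG cytosines marked methylated in ``state``;
    non-CpG cytosines convert unconditionally.  Length is preserved.
    """
    seq = sequence.upper()
    state = state or MethylationState.unmethylated()
    state.validate(seq)
    protected = state.methylated_positions()
    return "".join(
        "T" if c == "C" and i not in protected else c for i, c in enumerate(seq)
    )


@dataclass(frozen=True)
class RestrictionSite:
    start: int                 # 0-based offset of the recognition string
    recognition: str
    cpg_positions: tuple[int, ...]  # absolute positions of CpG cytosines inside
    dependent: bool            # True iff every C in the string is CpG-context

    @property
    def end(self) -> int:
        return self.start + len(self.recognition)


def find_methylation_dependent_sites(
    sequence: str, recognition: str = "ACGGCG"
) -> list[RestrictionSite]:
    """Scan one strand for recognition sites and their internal CpGs.

    A site is methylation-dependent iff every cytosine of the recognition
    string is in CpG context in the actual sequence: then the site survives
    bisulfite conversion exactly when all of its CpGs are methylated.
    Overlapping occurrences are all reported.
    """
    seq = sequence.upper()
    rec = recognition.upper()
    sites = []
    for m in re.finditer(f"(?={re.escape(rec)})", seq):
        s = m.start()
        c_positions = [s + i for i, ch in enumerate(rec) if ch == "C"]
        cpgs = tuple(p for p in c_positions
                     if p + 1 < len(seq) and seq[p + 1] == "G")
        sites.append(RestrictionSite(s, rec, cpgs, len(cpgs) == len(c_positions)))
    return sites


# ---------------------------------------------------------------------------
# candidate selection

@dataclass
class CandidateSelection:
    kept: list[LtrElement]
    dropped: dict[str, int] = field(default_factory=dict)


def _interval_overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def select_candidates(
    catalog: Sequence[LtrElement],
    annotations: Sequence[RepeatAnnotation] = (),
    shared_kmer: int = 30,
    max_repeat_cover: float = 0.5,
) -> CandidateSelection:
    """Reduce a paired catalog to assayable 5' LTRs with unique flanks.

    Keeps only elements annotated ``five_prime_of_pair`` (the 3' copies are
    duplicates of the same insertion; solo LTRs lack the full proviral
    structure).  An element is then dropped as repetitive-flank if its assay
    flank (the unique genomic side, ``flank_up``) shares an exact match of
    ``shared_kmer`` nt with any other candidate's flank, or if at least
    ``max_repeat_cover`` of the flank interval is covered by other repeat
    annotations.
    """
    five = [e for e in catalog if e.structure == FIVE_PRIME]
    dropped = {"not_five_prime_pair": len(catalog) - len(five),
               "shared_flank": 0, "annotated_flank": 0}
    # exact shared k-mers across candidate flanks
    owners: dict[str, set[int]] = {}
    for idx, e in enumerate(five):
        f = e.flank_up.upper()
        for i in range(0, max(0, len(f) - shared_kmer + 1)):
            owners.setdefault(f[i:i + shared_kmer], set()).add(idx)
    kept: list[LtrElement] = []
    for idx, e in enumerate(five):
        f = e.flank_up.upper()
        shared = any(
            len(owners[f[i:i + shared_kmer]]) > 1
            for i in range(0, max(0, len(f) - shared_kmer + 1))
        )
        if shared:
            dropped["shared_flank"] += 1
            continue
        # genomic interval of the assay flank (element orientation aware)
        flank_len = len(e.flank_up)
        if e.strand == "+":
            f0, f1 = e.start - flank_len, e.start
        else:
            f0, f1 = e.end, e.end + flank_len
        covered = 0
        for a in annotations:
            if a.chrom != e.chrom:
                continue
            if a.start - 1 == e.start and a.end == e.end:
                continue  # the element's own annotation
            covered += _interval_overlap(f0, f1, a.start - 1, a.end)
        if flank_len and covered / flank_len >= max_repeat_cover:
            dropped["annotated_flank"] += 1
            continue
        kept.append(e)
    return CandidateSelection(kept, dropped)


# ---------------------------------------------------------------------------
# primer design

@dataclass
class AssayConfig:
    recognition: str = "ACGGCG"
    cut_offset: int = 12          # nt downstream of the recognition 3' end
    primer_len_min: int = 18
    primer_len_max: int = 29
    amplicon_min: int = 150
    amplicon_max: int = 1300
    tm_min: float = 45.0
    tm_max: float = 60.0
    tm_method: str = "wallace"    # or "nn" (nearest-neighbor)
    site_primer_gap: int = 30     # min nt between site and either primer
    pcr_cycles: int = 45
    anneal_temp: float = 52.0


@dataclass
class CobraAssay:
    element_id: str
    forward_primer: str           # template-sense, may contain Y
    reverse_primer: str           # reverse-complement sense, may contain R
    amplicon_start: int           # on the assayed (antisense) strand
    amplicon_end: int
    amplicon_seq: str             # unconverted assayed strand
    amplicon_converted: str       # fully-methylated conversion
    cpg_sites: tuple[int, ...]    # amplicon-local CpG positions, in order
    diagnostic_cpgs: tuple[int, ...]  # 1-based numbers of site-internal CpGs
    site_positions: tuple[int, ...] = ()  # amplicon-local recognition starts
    predicted_fragments: tuple[int, ...] = ()
    pcr_cycles: int = 45
    anneal_temp: float = 52.0


def primer_tm(seq: str, method: str = "wallace") -> float:
    """Melting temperature of a concrete (non-degenerate) oligo."""
    seq = seq.upper()
    if method == "wallace":
        at = seq.count("A") + seq.count("T")
        gc = seq.count("G") + seq.count("C")
        return 2.0 * at + 4.0 * gc
    if method == "nn":
        from Bio.SeqUtils import MeltingTemp
        return float(MeltingTemp.Tm_NN(seq))
    raise ValueError(f"unknown Tm method {method!r}")


def _degenerate_forward(template_window: str, assayed: str, offset: int) -> str:
    """Y at CpG cytosine positions (in assayed-strand coordinates)."""
    out = []
    for i, ch in enumerate(template_window):
        p = offset + i
        if assayed[p] == "C" and p + 1 < len(assayed) and assayed[p + 1] == "G":
            out.append("Y")
        else:
            out.append(ch)
    return "".join(out)


_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "Y": "R", "R": "Y"}


def _revcomp_degenerate(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


def design_primers(
    element_seq: str,
    flank: str,
    config: AssayConfig | None = None,
    element_id: str = "",
) -> CobraAssay:
    """Design a junction-spanning CoBRA assay for one element.

    The template is the bisulfite-converted antisense strand of
    ``flank + element`` (fully-methylated conversion: CpG cytosines retained
    as C, then degenerate in primers).  On that strand the element occupies
    the 5' portion and the unique flank the 3' portion, so the forward
    primer (element-internal, 5' end of the amplicon) is a direct window of
    the template and the reverse primer (flank-internal) is a reverse
    complement window.  The amplicon must fall in the configured length
    window and contain at least one methylation-dependent site at least
    ``site_primer_gap`` nt away from both primers.

    Raises :class:`AssayDesignError` naming the first constraint that could
    not be satisfied.
    """
    cfg = config or AssayConfig()
    element_seq = element_seq.upper()
    flank = flank.upper()
    if not element_seq:
        raise AssayDesignError("empty element sequence")
    Le, Lf = len(element_seq), len(flank)
    assayed = revcomp(flank + element_seq)  # [element_rc][flank_rc]
    template = bisulfite_convert(assayed, MethylationState.fully_methylated(assayed))

    sites = [s for s in find_methylation_dependent_sites(assayed, cfg.recognition)
             if s.dependent]
    if not sites:
        raise AssayDesignError("no methylation-dependent site")

    def tm_ok(window: str) -> bool:
        if "N" in window:
            return False
        return cfg.tm_min <= primer_tm(window, cfg.tm_method) <= cfg.tm_max

    failure = "site too close to primer"
    for site in sites:
        # forward primer: [fs, fe) inside the element zone [0, Le),
        # ending at least site_primer_gap before the site
        fe_hi = min(site.start - cfg.site_primer_gap, Le)
        if fe_hi < cfg.primer_len_min:
            failure = "site too close to primer"
            continue
        chosen_fwd = None
        for fe in range(fe_hi, cfg.primer_len_min - 1, -1):
            for ln in range(cfg.primer_len_min, cfg.primer_len_max + 1):
                fs = fe - ln
                if fs < 0:
                    break
                if tm_ok(template[fs:fe]):
                    chosen_fwd = (fs, fe)
                    break
            if chosen_fwd:
                break
        if chosen_fwd is None:
            failure = "no forward primer"
            continue
        fs, fe = chosen_fwd
        # reverse primer: [rs, re) inside the flank zone [Le, Le+Lf),
        # starting at least site_primer_gap after the site
        rs_lo = max(Le, site.end + cfg.site_primer_gap)
        chosen_rev = None
        for rs in range(rs_lo, Le + Lf - cfg.primer_len_min + 1):
            for ln in range(cfg.primer_len_min, cfg.primer_len_max + 1):
                re_ = rs + ln
                if re_ > Le + Lf:
                    break
                amp_len = re_ - fs
                if amp_len > cfg.amplicon_max:
                    break
                if amp_len < cfg.amplicon_min:
                    continue
                if tm_ok(template[rs:re_]):
                    chosen_rev = (rs, re_)
                    break
            if chosen_rev:
                break
        if chosen_rev is None:
            failure = "no reverse primer"
            continue
        rs, re_ = chosen_rev
        fwd = _degenerate_forward(template[fs:fe], assayed, fs)
        rev_window = _degenerate_forward(template[rs:re_], assayed, rs)
        rev = _revcomp_degenerate(rev_window)
        amp = assayed[fs:re_]
        amp_conv = template[fs:re_]
        cpgs = tuple(p - fs for p in range(fs, re_ - 1)
                     if assayed[p] == "C" and assayed[p + 1] == "G")
        diag = tuple(i + 1 for i, p in enumerate(cpgs)
                     if p + fs in site.cpg_positions)
        frags = in_silico_digest(
            amp, MethylationState.fully_methylated(amp), cfg.recognition,
            cfg.cut_offset)
        local_sites = tuple(
            s.start
            for s in find_methylation_dependent_sites(amp, cfg.recognition)
            if s.dependent
        )
        return CobraAssay(
            element_id=element_id,
            forward_primer=fwd,
            reverse_primer=rev,
            amplicon_start=fs,
            amplicon_end=re_,
            amplicon_seq=amp,
            amplicon_converted=amp_conv,
            cpg_sites=cpgs,
            diagnostic_cpgs=diag,
            site_positions=local_sites,
            predicted_fragments=tuple(frags),
            pcr_cycles=cfg.pcr_cycles,
            anneal_temp=cfg.anneal_temp,
        )
    raise AssayDesignError(failure)


def in_silico_digest(
    amplicon: str,
    state: MethylationState | None = None,
    recognition: str = "ACGGCG",
    cut_offset: int = 12,
) -> list[int]:
    """Fragment lengths of the amplicon after conversion-dependent digestion.

    The amplicon is bisulfite-converted under ``state``; every recognition
    site that survives conversion cuts ``cut_offset`` nt downstream of its
    3' end (single-strand fragment model; a cut falling beyond the amplicon
    end does not happen).  Fully unmethylated templates return a single
    full-length fragment.  Fragment lengths always sum to the amplicon
    length.
    """
    conv = bisulfite_convert(amplicon, state)
    rec = recognition.upper()
    cuts = sorted({
        m.start() + len(rec) + cut_offset
        for m in re.finditer(f"(?={re.escape(rec)})", conv)
        if m.start() + len(rec) + cut_offset <= len(conv)
    })
    bounds = [0] + cuts + [len(conv)]
    return [b - a for a, b in zip(bounds, bounds[1:]) if b > a]


def verify_assay(
    assay: CobraAssay,
    element_seq: str,
    flank: str,
    config: AssayConfig | None = None,
) -> list[str]:
    """Independent constraint re-verification of an emitted assay.

    Recomputes the template from the element and flank sequences and checks
    every design constraint from scratch; returns a list of violation
    descriptions (empty means the assay checks out).
    """
    cfg = config or AssayConfig()
    problems: list[str] = []
    element_seq, flank = element_seq.upper(), flank.upper()
    Le, Lf = len(element_seq), len(flank)
    assayed = revcomp(flank + element_seq)
    template = bisulfite_convert(assayed, MethylationState.fully_methylated(assayed))
    fs, re_ = assay.amplicon_start, assay.amplicon_end
    fe = fs + len(assay.forward_primer)
    rs = re_ - len(assay.reverse_primer)
    if not (0 <= fs < fe <= Le):
        problems.append("forward primer not fully inside element")
    if not (Le <= rs < re_ <= Le + Lf):
        problems.append("reverse primer not fully inside flank")
    if assay.amplicon_seq != assayed[fs:re_]:
        problems.append("amplicon sequence mismatch")
    for ln, label in ((len(assay.forward_primer), "forward"),
                      (len(assay.reverse_primer), "reverse")):
        if not (cfg.primer_len_min <= ln <= cfg.primer_len_max):
            problems.append(f"{label} primer length {ln} out of range")
    if not (cfg.amplicon_min <= re_ - fs <= cfg.amplicon_max):
        problems.append(f"amplicon length {re_ - fs} out of range")
    # primer sequences match the template with Y/R exactly at CpG cytosines
    expect_fwd = _degenerate_forward(template[fs:fe], assayed, fs)
    if assay.forward_primer != expect_fwd:
        problems.append("forward primer does not match converted template")
    expect_rev = _revcomp_degenerate(_degenerate_forward(template[rs:re_], assayed, rs))
    if assay.reverse_primer != expect_rev:
        problems.append("reverse primer does not match converted template")
    for primer, label in ((assay.forward_primer, "forward"),
                          (assay.reverse_primer, "reverse")):
        concrete = primer.replace("Y", "C").replace("R", "G")
        tm = primer_tm(concrete, cfg.tm_method)
        if not (cfg.tm_min <= tm <= cfg.tm_max):
            problems.append(f"{label} primer Tm {tm:.1f} out of window")
    sites = [s for s in find_methylation_dependent_sites(assay.amplicon_seq,
                                                         cfg.recognition)
             if s.dependent]
    ok_sites = [s for s in sites
                if s.start >= len(assay.forward_primer) + cfg.site_primer_gap
                and s.end <= (re_ - fs) - len(assay.reverse_primer) - cfg.site_primer_gap]
    if not ok_sites:
        problems.append("no methylation-dependent site clear of both primers")
    frags = in_silico_digest(
        assay.amplicon_seq, MethylationState.fully_methylated(assay.amplicon_seq),
        cfg.recognition, cfg.cut_offset)
    if sum(frags) != re_ - fs:
        problems.append("digest fragments do not conserve amplicon length")
    if tuple(frags) != tuple(assay.predicted_fragments):
        problems.append("predicted fragments mismatch")
    return problems
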