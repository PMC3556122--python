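"""Repeat catalog: RepeatMasker annotation parsing, filtering and LTR extraction.

The entry point of the pipeline is a RepeatMasker ``.out`` annotation table
plus the genome it was computed on.  This module parses that dialect, applies
the subtype/length/chromosome filters used to reduce a genome-wide LTR scan
to a single retroviral LTR subfamily (e.g. ``IAPLTR1_Mm``), extracts each
element with up to 400 nt of flanking sequence for assay design, and assigns
paired (5'/3' of one proviral insertion) versus solo-LTR structure.

Coordinate conventions: :class:`RepeatAnnotation` mirrors the ``.out`` file
and is 1-based inclusive; :class:`LtrElement` is internal and 0-based
half-open; BED export is 0-based half-open.  Conversion happens only at the
I/O boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence, TextIO

from Bio.Seq import Seq

__all__ = [
    "RepeatAnnotation",
    "LtrElement",
    "FilterResult",
    "parse_repeatmasker_out",
    "write_repeatmasker_out",
    "filter_subtype",
    "strand_census",
    "extract_with_flanks",
    "pair_ltrs",
    "scan_genome",
    "load_genome",
    "write_bed",
    "write_catalog_tsv",
    "write_elements_fasta",
]

SOLO = "solo_ltr"
FIVE_PRIME = "five_prime_of_pair"
THREE_PRIME = "three_prime_of_pair"


class RepeatMaskerFormatError(ValueError):
    """Raised for an unreadable header or malformed record lines."""


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class RepeatAnnotation:
    """One RepeatMasker hit, in the file's own 1-based inclusive coordinates."""

    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str  # "+" or "-"
    repeat_name: str
    repeat_class: str = ""
    percent_div: float = 0.0
    score: int = 0

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad coordinates {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class LtrElement:
    """An extracted LTR instance in internal 0-based half-open coordinates.

    ``sequence`` is strand-oriented (the element's own 5'->3'); ``flank_up``
    and ``flank_down`` are likewise in element orientation, so for a minus
    strand element ``flank_up`` is the reverse complement of the genomic
    sequence immediately 3' of the hit.
    """

    id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    sequence: str
    flank_up: str = ""
    flank_down: str = ""
    structure: str = SOLO
    clade: str | None = None
    truncated_flank: bool = False


_HEADER_TOKENS = ("SW", "score")


def parse_repeatmasker_out(stream: TextIO | str) -> list[RepeatAnnotation]:
    """Parse RepeatMasker ``.out`` text into annotations.

    Accepts the standard layout: two header lines, a blank line, then
    whitespace-delimited records.  The strand column's ``C`` (complement) is
    mapped to ``-``.  Malformed records raise
    :class:`RepeatMaskerFormatError` naming the offending line numbers.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    annotations: list[RepeatAnnotation] = []
    errors: list[str] = []
    saw_any = False
    for lineno, line in enumerate(stream, start=1):
        txt = line.strip()
        if not txt:
            continue
        first = txt.split()[0]
        if first in _HEADER_TOKENS or txt.startswith("There were no"):
            saw_any = True
            continue
        saw_any = True
        fields = txt.split()
        if len(fields) < 13:
            errors.append(f"line {lineno}: expected >=13 fields, got {len(fields)}")
            continue
        try:
            score = int(fields[0])
            div = float(fields[1])
            chrom = fields[4]
            start = int(fields[5])
            end = int(fields[6])
            strand = {"+": "+", "C": "-", "-": "-"}[fields[8]]
            name = fields[9]
            rclass = fields[10]
            annotations.append(
                RepeatAnnotation(chrom, start, end, strand, name, rclass, div, score)
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"line {lineno}: {exc}")
    if not saw_any:
        # A .out file always carries its banner; an empty stream is not one.
        raise RepeatMaskerFormatError("unreadable or empty RepeatMasker header")
    if errors:
        raise RepeatMaskerFormatError("; ".join(errors))
    return annotations


_OUT_HEADER = (
    "   SW  perc perc perc  query     position in query    matching "
    "repeat      position in repeat\n"
    "score  div. del. ins.  sequence  begin end   (left)   repeat   "
    "class/family  begin end (left) ID\n"
    "\n"
)


def write_repeatmasker_out(annotations: Iterable[RepeatAnnotation]) -> str:
    """Serialize annotations back to the ``.out`` dialect (round-trips)."""
    lines = [_OUT_HEADER.rstrip("\n")]
    for i, a in enumerate(annotations, start=1):
        strand = "+" if a.strand == "+" else "C"
        lines.append(
            f"{a.score:>5} {a.percent_div:4.1f}  0.0  0.0 {a.chrom} "
            f"{a.start} {a.end} (0) {strand} {a.repeat_name} "
            f"{a.repeat_class or 'LTR/ERVK'} 1 {a.length} (0) {i}"
        )
    return "\n".join(lines) + "\n"


@dataclass
class FilterResult:
    kept: list[RepeatAnnotation]
    removed: dict[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())


def _is_chromosomal(chrom: str, allowed: set[str] | None) -> bool:
    if allowed is not None:
        return chrom in allowed
    return "random" not in chrom and "Un" not in chrom and "hap" not in chrom


def filter_subtype(
    annotations: Sequence[RepeatAnnotation],
    subtype_name: str,
    min_length: int = 330,
    allowed_chroms: Iterable[str] | None = None,
) -> FilterResult:
    """Keep hits of one repeat subtype that are long enough and chromosomal.

    Removal reasons are counted with precedence subtype > short > unmapped so
    each dropped record is counted exactly once; input order is preserved.
    """
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    allowed = set(allowed_chroms) if allowed_chroms is not None else None
    kept: list[RepeatAnnotation] = []
    removed = {"subtype": 0, "short": 0, "unmapped": 0}
    for a in annotations:
        if a.repeat_name != subtype_name:
            removed["subtype"] += 1
        elif a.length < min_length:
            removed["short"] += 1
        elif not _is_chromosomal(a.chrom, allowed):
            removed["unmapped"] += 1
        else:
            kept.append(a)
    return FilterResult(kept, removed)


def strand_census(annotations: Iterable[RepeatAnnotation]) -> dict[str, int]:
    """Count sense ("+") versus antisense ("-") annotations."""
    census = {"sense": 0, "antisense": 0}
    for a in annotations:
        census["sense" if a.strand == "+" else "antisense"] += 1
    return census


def load_genome(path: str) -> dict[str, str]:
    """Read a FASTA file into a name -> uppercase sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def extract_with_flanks(
    genome: Mapping[str, str],
    annotation: RepeatAnnotation,
    flank: int = 400,
    element_id: str | None = None,
) -> LtrElement:
    """Extract the element sequence plus up to ``flank`` nt on each side.

    Output is strand-oriented: on the minus strand the element sequence and
    both flanks are reverse-complemented and up/down are swapped so that
    ``flank_up`` always precedes the element's own 5' end.  Flanks shorter
    than ``flank`` (contig edge) set ``truncated_flank``.
    """
    if annotation.chrom not in genome:
        raise KeyError(f"sequence {annotation.chrom!r} not in genome")
    contig = genome[annotation.chrom]
    start0 = annotation.start - 1
    end0 = annotation.end
    if end0 > len(contig):
        raise IndexError(
            f"{annotation.chrom}:{annotation.start}-{annotation.end} exceeds "
            f"contig length {len(contig)}"
        )
    left = contig[max(0, start0 - flank): start0]
    body = contig[start0:end0]
    right = contig[end0: end0 + flank]
    truncated = len(left) < flank or len(right) < flank
    if annotation.strand == "+":
        seq, up, down = body, left, right
    else:
        seq, up, down = revcomp(body), revcomp(right), revcomp(left)
    return LtrElement(
        id=element_id or f"{annotation.chrom}:{annotation.start}-{annotation.end}",
        chrom=annotation.chrom,
        start=start0,
        end=end0,
        strand=annotation.strand,
        sequence=seq,
        flank_up=up,
        flank_down=down,
        truncated_flank=truncated,
    )


def build_catalog(
    genome: Mapping[str, str],
    annotations: Sequence[RepeatAnnotation],
    flank: int = 400,
    id_prefix: str = "IAP",
    id_start: int = 1,
) -> list[LtrElement]:
    """Extract all annotations, assigning stable unique ids IAP<n>."""
    elements = []
    for i, a in enumerate(annotations):
        elements.append(
            extract_with_flanks(genome, a, flank, element_id=f"{id_prefix}{id_start + i}")
        )
    return elements


def pair_ltrs(
    elements: Sequence[LtrElement],
    min_gap: int = 3000,
    max_gap: int = 8000,
) -> list[LtrElement]:
    """Assign paired/solo structure by the inner gap between neighbours.

    Two same-chromosome, same-strand elements whose inner gap (bases between
    the end of the left and the start of the right element) lies in
    ``[min_gap, max_gap]`` form one proviral insertion; the default window
    spans the ~5.4 kb truncated and ~7.2 kb full-length IAP bodies.  Pairing
    is greedy left-to-right with nearest-neighbour preference; each element
    joins at most one pair; everything else is a solo LTR.  For plus-strand
    pairs the left element is the 5' LTR; for minus-strand pairs element
    orientation is reversed, so the left element is the 3' LTR.
    """
    ordered = sorted(range(len(elements)), key=lambda i: (elements[i].chrom, elements[i].start))
    out = [replace(e, structure=SOLO) for e in elements]
    paired: set[int] = set()
    for pos, i in enumerate(ordered):
        if i in paired:
            continue
        ei = out[i]
        best: tuple[int, int] | None = None  # (gap, index)
        for j in ordered[pos + 1:]:
            if j in paired:
                continue
            ej = out[j]
            if ej.chrom != ei.chrom:
                break
            gap = ej.start - ei.end
            if gap > max_gap:
                break
            if ej.strand != ei.strand or gap < min_gap:
                continue
            if best is None or gap < best[0]:
                best = (gap, j)
        if best is not None:
            j = best[1]
            if ei.strand == "+":
                out[i].structure, out[j].structure = FIVE_PRIME, THREE_PRIME
            else:
                out[i].structure, out[j].structure = THREE_PRIME, FIVE_PRIME
            paired.update((i, j))
    return out


def scan_genome(
    genome: Mapping[str, str],
    consensus: str,
    max_divergence: float = 0.25,
    min_length: int = 330,
    repeat_name: str = "IAPLTR1_Mm",
) -> list[RepeatAnnotation]:
    """Naive consensus-matching scanner for synthetic genomes.

    Iterated best-infix edit-distance search (edlib) on both strands, masking
    each hit before re-searching, until the best remaining hit exceeds
    ``max_divergence`` edits per consensus base.  This is a toy stand-in used
    to exercise the pipeline on simulated genomes; real genomes are annotated
    by RepeatMasker and enter through :func:`parse_repeatmasker_out`.
    """
    import edlib

    consensus = consensus.upper()
    max_ed = int(max_divergence * len(consensus))
    hits: list[RepeatAnnotation] = []
    for chrom, seq in genome.items():
        for strand in ("+", "-"):
            target = list(seq if strand == "+" else revcomp(seq))
            while True:
                res = edlib.align(consensus, "".join(target), mode="HW",
                                  task="locations", k=max_ed)
                if res["editDistance"] < 0 or not res["locations"]:
                    break
                loc0, loc1 = res["locations"][0]
                length = loc1 - loc0 + 1
                if length >= min_length:
                    if strand == "+":
                        start, end = loc0 + 1, loc1 + 1
                    else:
                        start = len(seq) - loc1
                        end = len(seq) - loc0
                    hits.append(
                        RepeatAnnotation(
                            chrom, start, end, strand, repeat_name, "LTR/ERVK",
                            round(100.0 * res["editDistance"] / len(consensus), 1),
                            score=len(consensus) - res["editDistance"],
                        )
                    )
                target[loc0: loc1 + 1] = "N" * length
    hits.sort(key=lambda a: (a.chrom, a.start))
    return hits


# ---------------------------------------------------------------------------
# exports

def write_bed(elements: Iterable[LtrElement], path: str) -> None:
    """BED6 of elements (0-based half-open, score column = 0)."""
    with open(path, "w") as fh:
        for e in elements:
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.id}\t0\t{e.strand}\n")


def write_catalog_tsv(elements: Iterable[LtrElement], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("id\tchrom\tstart\tend\tstrand\tstructure\tclade\n")
        for e in elements:
            fh.write(
                f"{e.id}\t{e.chrom}\t{e.start}\t{e.end}\t{e.strand}\t"
                f"{e.structure}\t{e.clade or ''}\n"
            )


def write_elements_fasta(elements: Iterable[LtrElement], path: str,
                         with_flanks: bool = False) -> None:
    with open(path, "w") as fh:
        for e in elements:
            seq = e.flank_up + e.sequence + e.flank_down if with_flanks else e.sequence
            fh.write(f">{e.id}\n{seq}\n")
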