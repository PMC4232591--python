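"""Upstream-region extraction and IUPAC degenerate cis-element scanning.

The scanner looks for the eight circadian promoter elements (E-box, D-box,
RRE, GRE, PPRE, CREB, HSE, CBP) written in IUPAC degenerate nucleotide code in
fixed-length windows upstream of the translation start (ATG).  Matching is
exact degenerate-word comparison (per-position symbol sets, not regular
expressions); a subject ``N`` matches nothing except a pattern ``N``, which
keeps counts conservative on masked sequence.

Positions are reported relative to the ATG: -1 is the base immediately 5' of
the start codon.  Minus-strand matches are reported at the position of the
match's 5'-most base on the plus (window) strand with strand "-".  Both
strands are scanned by default; for reverse-complement-palindromic patterns
(such as the E-box CACGTG) the mirrored minus-strand copies are deduplicated
by default.
"""

from __future__ import annotations

from dataclasses import dataclass

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def revcomp_iupac(pattern: str) -> str:
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(pattern))


@dataclass(frozen=True)
class MotifDef:
    name: str
    pattern: str

    def __post_init__(self):
        if len(self.pattern) < 4:
            raise ValueError(f"motif {self.name}: pattern shorter than 4")
        for c in self.pattern:
            if c not in IUPAC_SETS:
                raise ValueError(f"motif {self.name}: illegal IUPAC symbol {c!r}")

    @property
    def is_palindromic(self) -> bool:
        return revcomp_iupac(self.pattern) == self.pattern


#: The eight circadian cis-elements searched in clock-gene promoters.
CLOCK_MOTIFS = [
    MotifDef("E-box", "CACGTG"),
    MotifDef("D-box", "TTATGYAA"),
    MotifDef("RRE", "WAWNTRGGTCA"),
    MotifDef("GRE", "ACANNNTGTTCT"),
    MotifDef("PPRE", "TGACCY"),
    MotifDef("CREB", "TGACGTMA"),
    MotifDef("HSE", "NGAANNGAANNTTCN"),
    MotifDef("CBP", "TKGNGAAK"),
]


@dataclass(frozen=True)
class MotifMatch:
    gene: str
    motif: str
    position: int  # relative to ATG; -1 = base immediately 5' of the ATG
    strand: str  # '+' or '-', relative to the gene's coding strand
    matched: str


def expand_iupac(pattern: str):
    """Return ``(matcher, expansion_count)`` for an IUPAC pattern.

    ``matcher(word)`` is True exactly for the concrete words in the pattern's
    product set; the count is the product of per-symbol degeneracies.  A
    subject 'N' is accepted only where the pattern itself has 'N'.
    """
    sets = []
    count = 1
    for c in pattern:
        if c not in IUPAC_SETS:
            raise ValueError(f"illegal IUPAC symbol {c!r}")
        allowed = IUPAC_SETS[c]
        count *= len(allowed)
        sets.append((frozenset(allowed), c == "N"))

    def matcher(word: str) -> bool:
        if len(word) != len(sets):
            return False
        for ch, (allowed, pat_is_n) in zip(word, sets):
            if ch == "N":
                if not pat_is_n:
                    return False
            elif ch not in allowed:
                return False
        return True

    return matcher, count


def _scan_one_strand(seq: str, motif: MotifDef):
    matcher, _ = expand_iupac(motif.pattern)
    k = len(motif.pattern)
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        if matcher(word):
            yield i, word


def scan(
    sequence: str,
    motifs=CLOCK_MOTIFS,
    both_strands: bool = True,
    dedup_palindromes: bool = True,
    gene: str = "",
) -> list[MotifMatch]:
    """All (overlapping) motif occurrences in an upstream window.

    The window is assumed to end immediately 5' of the ATG, so a match
    starting at window offset ``j`` has position ``j - len(sequence)``.
    """
    sequence = sequence.upper()
    n = len(sequence)
    out = []
    rc = revcomp(sequence) if both_strands else None
    for motif in motifs:
        k = len(motif.pattern)
        for i, word in _scan_one_strand(sequence, motif):
            out.append(MotifMatch(gene, motif.name, i - n, "+", word))
        if both_strands and not (dedup_palindromes and motif.is_palindromic):
            for i, word in _scan_one_strand(rc, motif):
                out.append(MotifMatch(gene, motif.name, (n - i - k) - n, "-", word))
    out.sort(key=lambda m: (m.motif, m.position, m.strand))
    return out


# ---------------------------------------------------------------------------
# Upstream extraction
# ---------------------------------------------------------------------------


@dataclass
class UpstreamRegion:
    """An extracted upstream window, oriented 5'->3' toward the ATG.

    ``genomic_start``/``genomic_end`` are 0-based half-open plus-strand
    coordinates of the window on its contig.
    """

    gene: str
    contig: str
    strand: str
    sequence: str
    genomic_start: int
    genomic_end: int
    truncated: bool

    def genomic_interval_of(self, position: int, length: int):
        """Genomic (start, end) of a match at gene-relative ``position``."""
        j = position + len(self.sequence)
        if self.strand == "+":
            s = self.genomic_start + j
            return s, s + length
        e = self.genomic_end - j
        return e - length, e


def load_genome(fasta_path) -> dict:
    from Bio import SeqIO

    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}


def open_annotation(gff_path):
    """In-memory gffutils database for a GFF3 annotation."""
    import gffutils

    return gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )


def extract_upstream(genome: dict, db, gene: str, length: int = 3000) -> UpstreamRegion:
    """The ``length`` bases immediately upstream of a gene's ATG.

    Plus strand: the window ends just before the CDS start.  Minus strand:
    the reverse complement of the bases just 3' (in genomic coordinates) of
    the CDS end.  Windows hitting a contig boundary are truncated and
    flagged.
    """
    import gffutils

    try:
        feat = db[gene]
    except gffutils.exceptions.FeatureNotFoundError:
        raise ValueError(f"gene {gene!r} absent from annotation") from None
    cds = list(db.children(feat, featuretype="CDS"))
    if not cds:
        raise ValueError(f"gene {gene!r} has no CDS; translation start undefined")
    contig = feat.seqid
    if contig not in genome:
        raise ValueError(f"contig {contig!r} of gene {gene!r} absent from genome")
    contig_seq = genome[contig]
    strand = feat.strand
    if strand == "+":
        atg0 = min(c.start for c in cds) - 1  # 0-based position of the A of ATG
        start = max(0, atg0 - length)
        window = contig_seq[start:atg0]
        truncated = atg0 - length < 0
        return UpstreamRegion(gene, contig, strand, window, start, atg0, truncated)
    if strand == "-":
        cds_end = max(c.end for c in cds)  # 1-based inclusive; ATG complement here
        end = min(len(contig_seq), cds_end + length)
        window = revcomp(contig_seq[cds_end:end])
        truncated = cds_end + length > len(contig_seq)
        return UpstreamRegion(gene, contig, strand, window, cds_end, end, truncated)
    raise ValueError(f"gene {gene!r} has undefined strand")


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_matches_tsv(matches, path) -> None:
    with open(path, "w") as fh:
        fh.write("# position is relative to the ATG: -1 = base immediately 5' of the start codon\n")
        fh.write("gene\tmotif\tposition\tstrand\tmatched\n")
        for m in matches:
            fh.write(f"{m.gene}\t{m.motif}\t{m.position}\t{m.strand}\t{m.matched}\n")


def write_matches_bed(matches, regions: dict, path) -> None:
    """BED6 (chrom, start, end, gene|motif, '.', genomic strand)."""
    with open(path, "w") as fh:
        for m in matches:
            reg = regions[m.gene]
            s, e = reg.genomic_interval_of(m.position, len(m.matched))
            gstrand = m.strand if reg.strand == "+" else ("-" if m.strand == "+" else "+")
            fh.write(f"{reg.contig}\t{s}\t{e}\t{m.gene}|{m.motif}\t.\t{gstrand}\n")
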