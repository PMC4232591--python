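"""Proteome indexing, cross-species best hits, reciprocal-best-hit orthology,
conservation aggregation and the cross-phylum intersection.

Best hits use local (Smith–Waterman) alignment with Karlin–Altschul E-values
at a fixed cutoff (1e-10 by default, the standalone BLASTP default used for
cross-proteome clock-protein searches).  Two proteins in different species
that are each other's best hit form a reciprocal best hit (RBH), the standard
1:1 orthology heuristic; protein isoform ids (a trailing lowercase letter
after a locus stem, e.g. F47F6.1b / F47F6.1c) collapse to the locus stem for
reciprocity and intersection.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from . import align as align_mod

log = logging.getLogger(__name__)

#: Isoform ids collapse to their locus stem for reciprocity/intersection.
ISOFORM_PATTERN = r"^(.*\d)[a-z]$"


def collapse_isoform(protein_id: str, pattern: str = ISOFORM_PATTERN) -> str:
    m = re.match(pattern, protein_id)
    return m.group(1) if m else protein_id


# ---------------------------------------------------------------------------
# Proteome database
# ---------------------------------------------------------------------------


@dataclass
class ProteomeDB:
    """An indexed species proteome: ordered records, searchable by id."""

    species: str
    records: list  # ordered (id, sequence)
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._index = {}
        for pos, (pid, _) in enumerate(self.records):
            if pid in self._index:
                raise ValueError(
                    f"duplicate id {pid!r} in proteome {self.species!r} "
                    f"(records {self._index[pid]} and {pos})"
                )
            self._index[pid] = pos

    @property
    def residue_count(self) -> int:
        return sum(len(s) for _, s in self.records)

    def __len__(self):
        return len(self.records)

    def __contains__(self, pid):
        return pid in self._index

    def get(self, pid: str) -> str:
        return self.records[self._index[pid]][1]

    def ids(self):
        return [i for i, _ in self.records]

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for pid, seq in self.records:
                fh.write(f">{pid}\n{seq}\n")


def index_proteome(fasta_path, species: str) -> ProteomeDB:
    """Read and index one species proteome FASTA (terminal '*' stripped)."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        records.append((rec.id, str(rec.seq).rstrip("*")))
    if not records:
        raise ValueError(f"{fasta_path}: empty proteome file")
    return ProteomeDB(species, records)


# ---------------------------------------------------------------------------
# Hits
# ---------------------------------------------------------------------------


@dataclass
class Hit:
    query: str
    target: str
    species: str
    score: float  # raw local-alignment score
    evalue: float


@dataclass
class OrthologPair:
    ce_id: str
    other_id: str | None
    forward: Hit | None
    reverse: Hit | None
    reciprocal: bool


@dataclass
class PairwiseStats:
    """Karlin–Altschul parameters for a scoring system."""

    lambda_: float
    K: float

    @classmethod
    def calibrate(cls, matrix, seed: int = 0, n_samples: int = 2000, **kw):
        lam, K = align_mod.fit_karlin_altschul(matrix, n_samples=n_samples, seed=seed, **kw)
        return cls(lam, K)


def best_hit(
    query_seq: str,
    db: ProteomeDB,
    matrix,
    stats: PairwiseStats,
    cutoff: float = 1e-10,
    query_id: str = "",
) -> Hit | None:
    """Best local-alignment hit of a query in a proteome, or None.

    Best = minimal E-value, ties broken by higher raw score then
    lexicographic target id.  An empty database or a best E-value above the
    cutoff yields None (logged with the best sub-threshold E for diagnosis).
    """
    if len(db) == 0:
        log.info("best_hit(%s -> %s): empty database", query_id, db.species)
        return None
    scores = align_mod.local_scores(query_seq, [s for _, s in db.records], matrix)
    n_res = db.residue_count
    m = len(query_seq)
    evals = np.array(
        [align_mod.evalue_pairwise(s, m, n_res, stats.lambda_, stats.K) for s in scores]
    )
    order = sorted(
        range(len(db)), key=lambda i: (evals[i], -scores[i], db.records[i][0])
    )
    best = order[0]
    e = float(evals[best])
    if e > cutoff:
        log.info(
            "best_hit(%s -> %s): no hit at E <= %g (best sub-threshold E = %g for %s)",
            query_id, db.species, cutoff, e, db.records[best][0],
        )
        return None
    return Hit(query_id, db.records[best][0], db.species, float(scores[best]), e)


def reciprocal_best_hit(
    ce_id: str,
    ce_db: ProteomeDB,
    other_db: ProteomeDB,
    matrix,
    stats: PairwiseStats,
    cutoff: float = 1e-10,
    isoform_pattern: str = ISOFORM_PATTERN,
) -> OrthologPair:
    """Forward best hit into the other species, reverse best hit back.

    The pair is reciprocal when the reverse best hit resolves to the original
    query id after isoform collapsing.
    """
    if ce_id not in ce_db:
        raise KeyError(f"{ce_id!r} not present in reference proteome {ce_db.species!r}")
    fwd = best_hit(ce_db.get(ce_id), other_db, matrix, stats, cutoff, query_id=ce_id)
    if fwd is None:
        return OrthologPair(ce_id, None, None, None, False)
    rev = best_hit(
        other_db.get(fwd.target), ce_db, matrix, stats, cutoff, query_id=fwd.target
    )
    reciprocal = rev is not None and collapse_isoform(
        rev.target, isoform_pattern
    ) == collapse_isoform(ce_id, isoform_pattern)
    return OrthologPair(ce_id, fwd.target, fwd, rev, reciprocal)


# ---------------------------------------------------------------------------
# Conservation table and intersection
# ---------------------------------------------------------------------------


@dataclass
class ConservationTable:
    """Rows = query clock proteins, columns = species, cells = ortholog id."""

    queries: list  # sorted query names
    species: list
    ce_hits: dict  # query -> reference-species protein id
    cells: dict  # (query, species) -> protein id or None

    def fully_conserved(self, query: str) -> bool:
        return all(self.cells.get((query, sp)) is not None for sp in self.species)

    def to_dataframe(self):
        import pandas as pd

        data = {
            "query": self.queries,
            "reference_hit": [self.ce_hits.get(q) for q in self.queries],
        }
        for sp in self.species:
            data[sp] = [self.cells.get((q, sp)) for q in self.queries]
        return pd.DataFrame(data)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, na_rep="None")


def conservation_matrix(
    accepted_ce_hits: list,
    ce_db: ProteomeDB,
    other_dbs: list,
    matrix,
    stats: PairwiseStats,
    cutoff: float = 1e-10,
    domain_check=None,
) -> ConservationTable:
    """Best conserved ortholog per species for each accepted reference hit.

    ``accepted_ce_hits`` is a list of ``(query_name, ce_protein_id)``.  A cell
    is filled only when the cross-species hit is reciprocal and (if a
    ``domain_check(protein_id, species)`` predicate is given) domain
    concordant.  Rows are sorted by query name.
    """
    queries = sorted(q for q, _ in accepted_ce_hits)
    ce_of = {q: pid for q, pid in accepted_ce_hits}
    cells = {}
    for q in queries:
        for db in other_dbs:
            pair = reciprocal_best_hit(ce_of[q], ce_db, db, matrix, stats, cutoff)
            ok = pair.reciprocal
            if ok and domain_check is not None:
                ok = domain_check(pair.other_id, db.species)
            cells[(q, db.species)] = pair.other_id if ok else None
    return ConservationTable(queries, [db.species for db in other_dbs], ce_of, cells)


def cross_phylum_intersection(
    insect_hits: list,
    mammal_hits: list,
    conservation: ConservationTable,
    include_flagged: bool = False,
    isoform_pattern: str = ISOFORM_PATTERN,
):
    """Reference-species loci hit from both query phyla and fully conserved.

    ``insect_hits``/``mammal_hits`` are lists of objects with attributes
    ``query``, ``target`` (reference protein id) and ``status``
    ('accepted'/'flagged').  Loci are compared at gene level after isoform
    collapsing.  Flagged-only support in a phylum excludes the locus unless
    ``include_flagged`` is set.  Returns ``(common_loci, exclusion_reasons)``
    where reasons maps each rejected candidate locus to why it fell out.
    """

    def loci(hits):
        out = {}
        for h in hits:
            if h.target is None:
                continue
            if not include_flagged and getattr(h, "status", "accepted") != "accepted":
                continue
            out.setdefault(collapse_isoform(h.target, isoform_pattern), []).append(h)
        return out

    ins = loci(insect_hits)
    mam = loci(mammal_hits)
    conserved_loci = {}
    for q in conservation.queries:
        pid = conservation.ce_hits.get(q)
        if pid is None:
            continue
        locus = collapse_isoform(pid, isoform_pattern)
        conserved_loci.setdefault(locus, False)
        if conservation.fully_conserved(q):
            conserved_loci[locus] = True

    common = set()
    reasons = {}
    for locus in set(ins) | set(mam) | set(conserved_loci):
        if locus not in ins:
            reasons[locus] = "no accepted insect-query hit"
        elif locus not in mam:
            reasons[locus] = "no accepted mammal-query hit"
        elif locus not in conserved_loci:
            reasons[locus] = "absent from conservation table"
        elif not conserved_loci[locus]:
            reasons[locus] = "not fully conserved across species"
        else:
            common.add(locus)
    return common, reasons


def write_hits_tsv(hits, path, status: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("query\ttarget\tspecies\tscore\tevalue\tstatus\n")
        for h in hits:
            st = (status or {}).get((h.query, h.target), "")
            fh.write(f"{h.query}\t{h.target}\t{h.species}\t{h.score:.1f}\t{h.evalue:.3g}\t{st}\n")
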