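"""Domain annotation of hit proteins and the domain-concordance acceptance rule.

A hit protein is annotated by scanning it with calibrated per-domain profile
HMMs (best-scoring, non-overlapping regions).  A hit is *accepted* when its
domain set contains the query's domain set (extra domains allowed, copy
number and order ignored); otherwise it is *flagged* — never dropped, so
reports can still print it, marked, the way discordant best hits are
highlighted in bold in published homolog tables.  Strict set equality is
available behind the ``rule`` switch.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import hmm as hmm_mod


@dataclass
class DomainRegion:
    domain: str
    start: int  # 0-based half-open on the protein
    end: int
    score: float  # Forward bits of the domain profile on the protein
    evalue: float


@dataclass
class DomainAnnotation:
    protein: str
    regions: list

    @property
    def domain_set(self) -> frozenset:
        return frozenset(r.domain for r in self.regions)

    def architecture(self) -> list:
        return [r.domain for r in self.regions]


@dataclass
class AcceptanceDecision:
    hit: object  # HmmHit (or any object with .target)
    query_domains: frozenset
    target_domains: frozenset
    status: str  # 'accepted' | 'flagged'

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


def annotate_domains(
    protein_id: str,
    sequence: str,
    domain_profiles: list,
    per_domain_threshold: float = 0.01,
) -> DomainAnnotation:
    """Best non-overlapping domain-profile regions on one protein.

    Each calibrated domain profile contributes its best Viterbi region when
    the Forward-score E-value (single-target) passes ``per_domain_threshold``.
    Overlaps are resolved greedily in favor of the higher score.
    """
    if not domain_profiles:
        raise ValueError("empty domain library")
    candidates = []
    for prof in domain_profiles:
        if not prof.calibrated:
            raise ValueError(f"domain profile {prof.name} is not calibrated")
        if len(sequence) == 0:
            continue
        score = hmm_mod.forward_score(prof, sequence)
        ev = hmm_mod.score_evalue(prof, score, 1, target_length=len(sequence))
        if ev > per_domain_threshold:
            continue
        _, path = hmm_mod.viterbi_trace(prof, sequence)
        start, end = hmm_mod.match_region(path)
        if end > start:
            candidates.append(DomainRegion(prof.name, start, end, float(score), float(ev)))
    candidates.sort(key=lambda r: (-r.score, r.start, r.domain))
    chosen = []
    for cand in candidates:
        if all(cand.end <= c.start or cand.start >= c.end for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda r: r.start)
    return DomainAnnotation(protein_id, chosen)


def accept_hits(
    hits: list,
    query_domain_set,
    annotations: dict,
    rule: str = "containment",
) -> list:
    """Apply the domain-concordance rule to a list of hits.

    ``annotations`` maps target protein id -> :class:`DomainAnnotation`.
    With ``rule='containment'`` (default) a hit is accepted iff its domain
    set is a superset of the query's; ``rule='equality'`` demands identity.
    Flagged hits are returned, not dropped.
    """
    if rule not in ("containment", "equality"):
        raise ValueError(f"unknown domain rule {rule!r}")
    qset = frozenset(query_domain_set)
    out = []
    for hit in hits:
        ann = annotations[hit.target]
        tset = ann.domain_set
        ok = tset >= qset if rule == "containment" else tset == qset
        out.append(AcceptanceDecision(hit, qset, tset, "accepted" if ok else "flagged"))
    return out


def write_annotations_tsv(annotations, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein\tdomain\tstart\tend\tscore\tevalue\n")
        for ann in annotations:
            for r in ann.regions:
                fh.write(
                    f"{ann.protein}\t{r.domain}\t{r.start}\t{r.end}\t"
                    f"{r.score:.3f}\t{r.evalue:.3g}\n"
                )
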