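"""Published clock-protein hit tables bundled as data.

The per-query best-hit tables (five query phyla against the C. elegans
proteome, with domain-discordant hits marked) and the cross-species
conservation matrix of the common clock components are shipped as TSV so the
conservation/intersection logic can be exercised on the real published hit
lists without any download.  Applying the cross-phylum intersection to these
tables reproduces the published count of clock components common to mammals,
insects and nematodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .orthology import ConservationTable, cross_phylum_intersection


def _data_path(name: str):
    return resources.files("nemaclock.data").joinpath(name)


def load_published_hits():
    """All published best-hit rows as a pandas DataFrame."""
    import pandas as pd

    with resources.as_file(_data_path("published_hits.tsv")) as p:
        df = pd.read_csv(p, sep="\t", keep_default_na=False)
    return df


def load_published_conservation() -> ConservationTable:
    """The published conservation matrix of common clock components."""
    import pandas as pd

    with resources.as_file(_data_path("published_conservation.tsv")) as p:
        df = pd.read_csv(p, sep="\t", keep_default_na=False)
    species = [c for c in df.columns if c not in ("mammal_query", "insect_query", "C_elegans")]
    queries = sorted(df["mammal_query"])
    rows = {r["mammal_query"]: r for _, r in df.iterrows()}
    ce_hits = {q: rows[q]["C_elegans"] for q in queries}
    cells = {
        (q, sp): (rows[q][sp] if rows[q][sp] not in ("", "None") else None)
        for q in queries
        for sp in species
    }
    return ConservationTable(queries, species, ce_hits, cells)


@dataclass
class PublishedHit:
    query: str
    target: str | None
    status: str
    evalue: str = ""
    common_name: str = ""


def published_phylum_hits(phylum: str) -> list:
    df = load_published_hits()
    out = []
    for _, r in df[df["phylum"] == phylum].iterrows():
        target = None if r["target"] == "None" else r["target"]
        out.append(PublishedHit(r["query"], target, r["status"], r["evalue"], r["common_name"]))
    return out


def published_common_components(include_flagged: bool = True):
    """Cross-phylum intersection applied to the published hit lists.

    With flagged hits included (the counting evident in the published common
    set, which keeps a locus whose mammal-query best hit is domain
    discordant), this reproduces the published seven common clock components.
    Returns ``(common_loci, exclusion_reasons)``.
    """
    insect = published_phylum_hits("insect")
    mammal = published_phylum_hits("mammal")
    conservation = load_published_conservation()
    return cross_phylum_intersection(
        insect, mammal, conservation, include_flagged=include_flagged
    )
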