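"""End-to-end orchestration of the homolog-discovery workflow.

Stages (in order): align seed ortholog sets -> build + calibrate profile
HMMs -> search the reference proteome -> domain-concordance filter ->
per-species best hit + reciprocal best hit -> conservation matrix ->
cross-phylum intersection -> promoter cis-element scan -> concatemer
phylogeny.  ``run`` executes the whole workflow on a synthetic benchmark from
a declarative config, writing TSV/Newick artifacts plus a manifest that lets
an unchanged re-run skip completed stages; ``render_reports`` formats the
published-table layouts from the stage outputs.

All thresholds default to the published protocol: HMM inclusion E <= 0.01,
pairwise best-hit cutoff E <= 1e-10, 3000 bp promoter windows, 1000 bootstrap
replicates, the eight-element IUPAC motif catalog.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import align as align_mod
from . import domains as dom_mod
from . import hmm as hmm_mod
from . import orthology as orth_mod
from . import phylo as phylo_mod
from . import promoters as prom_mod
from . import synthetic as syn_mod

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    n_families: int = 10
    n_species: int = 13
    n_decoys: int = 500
    hmm_inclusion: float = 0.01
    pairwise_cutoff: float = 1e-10
    domain_rule: str = "containment"
    include_flagged: bool = False
    upstream_len: int = 3000
    bootstrap_n: int = 1000
    gamma_alpha: float = 1.0
    calib_decoys: int = 2000
    calib_decoy_length: int = 200
    motifs: dict = field(
        default_factory=lambda: {m.name: m.pattern for m in prom_mod.CLOCK_MOTIFS}
    )
    output_dir: str = "runs/benchmark"

    def validate(self) -> None:
        for name in ("hmm_inclusion", "pairwise_cutoff", "upstream_len", "bootstrap_n", "gamma_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config: {name} must be positive")
        if self.n_species < 1 or self.n_families < 1:
            raise ValueError("config: species list and family count must be non-empty")
        if self.domain_rule not in ("containment", "equality"):
            raise ValueError(f"config: unknown domain rule {self.domain_rule!r}")

    def motif_defs(self):
        return [prom_mod.MotifDef(n, p) for n, p in self.motifs.items()]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()


# ---------------------------------------------------------------------------
# Reusable stage computations (in-memory; run() wraps them with artifacts)
# ---------------------------------------------------------------------------


def build_family_hmms(bench, config: PipelineConfig | None = None, seed: int = 0):
    """Align each phylum's seed ortholog set and build a calibrated profile.

    Returns ``{(phylum, family): ProfileHMM}`` plus the seed MSAs.
    """
    config = config or PipelineConfig()
    matrix = align_mod.blosum62()
    rng = np.random.default_rng(seed)
    hmms = {}
    msas = {}
    for phylum in sorted(bench.seed_sets):
        for fid in sorted(bench.seed_sets[phylum]):
            msa = align_mod.progressive_msa(bench.seed_sets[phylum][fid], matrix)
            msas[(phylum, fid)] = msa
            prof = hmm_mod.build_profile(msa, name=f"{phylum}:{fid}")
            hmm_mod.calibrate(
                prof,
                n_decoys=config.calib_decoys,
                decoy_length=config.calib_decoy_length,
                seed=int(rng.integers(0, 2**31)),
            )
            hmms[(phylum, fid)] = prof
    return hmms, msas


def build_domain_profiles(bench, config: PipelineConfig | None = None, seed: int = 0):
    """Calibrated single-domain profiles from seed-taxon domain instances.

    Domains evolve substitution-only, so instances of one domain are already
    columnwise homologous and stack directly into an MSA.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    instances = {d.id: [] for d in bench.domain_library}
    for phylum in sorted(bench.seed_sets):
        for fid in sorted(bench.seed_sets[phylum]):
            arch = bench.architecture(fid)
            for pid, seq in bench.seed_sets[phylum][fid]:
                for did, start, end in bench.truth.domain_coords[pid]:
                    instances[did].append((pid, seq[start:end]))
    profiles = {}
    for did, rows in sorted(instances.items()):
        if not rows:
            continue
        msa = align_mod.MSA(rows)
        prof = hmm_mod.build_profile(msa, name=did)
        hmm_mod.calibrate(
            prof,
            n_decoys=config.calib_decoys,
            decoy_length=config.calib_decoy_length,
            seed=int(rng.integers(0, 2**31)),
        )
        profiles[did] = prof
    return profiles


def search_reference(bench, hmms: dict, config: PipelineConfig | None = None):
    """hmmsearch every family profile against the reference proteome."""
    config = config or PipelineConfig()
    ref_db = bench.proteome_db(bench.reference)
    return {
        key: hmm_mod.hmmsearch(h, ref_db, inclusion=config.hmm_inclusion)
        for key, h in sorted(hmms.items())
    }


@dataclass
class FilteredHit:
    """A best reference-proteome hit with its domain-concordance status."""

    phylum: str
    query: str  # family id (the query clock-protein analog)
    target: str | None
    score: float | None
    evalue: float | None
    status: str  # accepted | flagged | none


def domain_filter_stage(bench, search_results, domain_profiles, config=None):
    """Keep each model's best included hit, accepted or flagged by domain rule."""
    config = config or PipelineConfig()
    ref_db = bench.proteome_db(bench.reference)
    annotations = {}
    out = []
    for (phylum, fid), hits in sorted(search_results.items()):
        included = [h for h in hits if h.included]
        if not included:
            out.append(FilteredHit(phylum, fid, None, None, None, "none"))
            continue
        best = included[0]
        if best.target not in annotations:
            annotations[best.target] = dom_mod.annotate_domains(
                best.target, ref_db.get(best.target), list(domain_profiles.values())
            )
        decision = dom_mod.accept_hits(
            [best], bench.architecture(fid), annotations, rule=config.domain_rule
        )[0]
        out.append(
            FilteredHit(phylum, fid, best.target, best.score, best.evalue, decision.status)
        )
    return out, annotations


def orthology_stage(bench, filtered_hits, config=None, stats=None, matrix=None):
    """Conservation matrix over the other species plus the intersection."""
    config = config or PipelineConfig()
    matrix = matrix or align_mod.blosum62()
    if stats is None:
        stats = orth_mod.PairwiseStats.calibrate(matrix, seed=config.seed)
    ce_db = bench.proteome_db(bench.reference)
    other_dbs = [bench.proteome_db(sp) for sp in bench.species[1:]]
    accepted = [
        (f"{h.phylum}:{h.query}", h.target)
        for h in filtered_hits
        if h.status == "accepted"
    ]
    conservation = orth_mod.conservation_matrix(
        accepted, ce_db, other_dbs, matrix, stats, cutoff=config.pairwise_cutoff
    )
    insect_hits = [h for h in filtered_hits if h.phylum == "insect" and h.target]
    mammal_hits = [h for h in filtered_hits if h.phylum == "mammal" and h.target]
    common, reasons = orth_mod.cross_phylum_intersection(
        insect_hits, mammal_hits, conservation, include_flagged=config.include_flagged
    )
    return conservation, common, reasons, stats


def promoter_stage(bench, config=None):
    """Extract upstream windows of the reference clock-gene analogs and scan."""
    config = config or PipelineConfig()
    if bench.genome is None:
        raise ValueError("benchmark was generated without a genome")
    import tempfile, os

    with tempfile.NamedTemporaryFile("w", suffix=".gff3", delete=False) as fh:
        fh.write(bench.gff_text)
        gff_path = fh.name
    try:
        db = prom_mod.open_annotation(gff_path)
    finally:
        os.unlink(gff_path)
    motifs = config.motif_defs()
    regions = {}
    matches = []
    for gene in sorted(bench.truth.motif_plants):
        region = prom_mod.extract_upstream(bench.genome, db, gene, config.upstream_len)
        regions[gene] = region
        matches.extend(
            prom_mod.scan(region.sequence, motifs, dedup_palindromes=True, gene=gene)
        )
    return regions, matches


def tree_stage(bench, config=None, seed: int = 0, n_bootstrap: int | None = None):
    """Concatemer NJ tree of the common families across the three taxa."""
    config = config or PipelineConfig()
    matrix = align_mod.blosum62()
    alignments = {}
    species_map = None
    for fid in sorted(bench.common_families):
        seqs = []
        for phylum in sorted(bench.seed_sets):
            if fid in bench.seed_sets[phylum]:
                seqs.extend(bench.seed_sets[phylum][fid])
        for sp in bench.species:
            pid = bench.truth.proteins[fid][sp]
            seq = dict(bench.proteomes[sp])[pid]
            seqs.append((pid, seq))
        alignments[fid] = align_mod.progressive_msa(seqs, matrix)
    # map species -> row id per family
    species_map = {}
    taxa = list(bench.species)
    for phylum in sorted(bench.seed_sets):
        anyfam = next(iter(sorted(bench.seed_sets[phylum])))
        for pid, _ in bench.seed_sets[phylum][anyfam]:
            taxa.append(pid.rsplit("_", 1)[0])
    taxa = sorted(set(taxa))
    for sp in taxa:
        species_map[sp] = {}
        for fid in alignments:
            for rid in alignments[fid].ids:
                if rid.rsplit("_", 1)[0] == sp:
                    species_map[sp][fid] = rid
    concat = phylo_mod.build_concatemer(alignments, species_map)
    n = n_bootstrap if n_bootstrap is not None else config.bootstrap_n
    correction = lambda p: phylo_mod.gamma_correct(p, config.gamma_alpha)
    tree = phylo_mod.bootstrap(concat, n=n, seed=seed, correction=correction)
    return concat, tree


# ---------------------------------------------------------------------------
# run(): artifact-writing orchestration with a resume manifest
# ---------------------------------------------------------------------------


def _stage(manifest, outdir, name, key, outputs, fn):
    """Run ``fn`` unless the manifest already records ``key`` with outputs present."""
    rec = manifest.get(name)
    paths = [outdir / o for o in outputs]
    if rec and rec.get("key") == key and all(p.exists() for p in paths):
        log.info("stage %s: up to date, skipped", name)
        return False
    t0 = time.time()
    fn()
    manifest[name] = {"key": key, "outputs": outputs, "seconds": round(time.time() - t0, 2)}
    log.info("stage %s: completed in %.1fs", name, time.time() - t0)
    return True


STAGES = ("generate", "models", "search", "filter", "orthology", "promoters", "tree")


def _needs(manifest, outdir, name, key, outputs) -> bool:
    rec = manifest.get(name)
    return not (rec and rec.get("key") == key and all((outdir / o).exists() for o in outputs))


def run(config: PipelineConfig, outdir=None, until: str | None = None) -> Path:
    """Execute the workflow (optionally only up to stage ``until``);
    idempotent for unchanged config."""
    config.validate()
    if until is not None and until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; stages are {STAGES}")
    outdir = Path(outdir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    cfg_key = config.digest()

    def wanted(stage: str) -> bool:
        return until is None or STAGES.index(stage) <= STAGES.index(until)

    def finish():
        config.to_yaml(outdir / "config.yaml")
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return outdir

    bench = syn_mod.make_benchmark(
        n_families=config.n_families,
        n_species=config.n_species,
        n_decoys=config.n_decoys,
        seed=config.seed,
        upstream_len=config.upstream_len,
    )

    def write_inputs():
        gen = outdir / "inputs"
        gen.mkdir(exist_ok=True)
        for sp in bench.species:
            syn_mod.write_fasta(bench.proteomes[sp], gen / f"{sp}.faa")
        with open(gen / "genome.fa", "w") as fh:
            for contig, seq in bench.genome.items():
                fh.write(f">{contig}\n{seq}\n")
        (gen / "genes.gff3").write_text(bench.gff_text)
        with open(gen / "truth_proteins.tsv", "w") as fh:
            fh.write("family\tspecies\tprotein\n")
            for fid in sorted(bench.truth.proteins):
                for sp in sorted(bench.truth.proteins[fid]):
                    fh.write(f"{fid}\t{sp}\t{bench.truth.proteins[fid][sp]}\n")
        with open(gen / "truth_motifs.tsv", "w") as fh:
            fh.write("gene\tmotif\tposition\tstrand\tword\n")
            for g in sorted(bench.truth.motif_plants):
                for mname, pos, strand, word in bench.truth.motif_plants[g]:
                    fh.write(f"{g}\t{mname}\t{pos}\t{strand}\t{word}\n")

    _stage(
        manifest, outdir, "generate", cfg_key,
        [f"inputs/{bench.species[0]}.faa", "inputs/genome.fa", "inputs/genes.gff3"],
        write_inputs,
    )
    if not wanted("models"):
        return finish()

    state = {}

    def do_models():
        hmms, msas = build_family_hmms(bench, config, seed=config.seed + 1)
        state["hmms"] = hmms
        mdir = outdir / "models"
        mdir.mkdir(exist_ok=True)
        adir = outdir / "alignments"
        adir.mkdir(exist_ok=True)
        for (phylum, fid), msa in msas.items():
            msa.to_fasta(adir / f"{phylum}_{fid}.afa")
        for (phylum, fid), prof in hmms.items():
            hmm_mod.save_hmm(prof, mdir / f"{phylum}_{fid}.nhmm")
        state["domain_profiles"] = build_domain_profiles(bench, config, seed=config.seed + 2)
        for did, prof in state["domain_profiles"].items():
            hmm_mod.save_hmm(prof, mdir / f"domain_{did}.nhmm")

    _stage(manifest, outdir, "models", cfg_key, [], do_models)
    if not wanted("search"):
        return finish()
    if "hmms" not in state:  # resumed run: reload serialized models
        state["hmms"] = {}
        state["domain_profiles"] = {}
        for p in sorted((outdir / "models").glob("*.nhmm")):
            prof = hmm_mod.load_hmm(p)
            if p.stem.startswith("domain_"):
                state["domain_profiles"][p.stem[len("domain_"):]] = prof
            else:
                phylum, fid = p.stem.split("_", 1)
                state["hmms"][(phylum, fid)] = prof

    def do_search():
        results = search_reference(bench, state["hmms"], config)
        state["search"] = results
        with open(outdir / "hits.tsv", "w") as fh:
            fh.write("model\ttarget\tspecies\tbits\tevalue\tincluded\n")
            for key in sorted(results):
                for h in results[key][:25]:
                    fh.write(
                        f"{h.model}\t{h.target}\t{bench.reference}\t"
                        f"{h.score:.2f}\t{h.evalue:.3g}\t{int(h.included)}\n"
                    )

    _stage(manifest, outdir, "search", cfg_key, ["hits.tsv"], do_search)
    if not wanted("filter"):
        return finish()
    filter_needed = _needs(manifest, outdir, "filter", cfg_key, ["filtered_hits.tsv"])
    if "search" not in state and filter_needed:
        state["search"] = search_reference(bench, state["hmms"], config)

    def do_filter():
        filtered, annotations = domain_filter_stage(
            bench, state["search"], state["domain_profiles"], config
        )
        state["filtered"] = filtered
        with open(outdir / "filtered_hits.tsv", "w") as fh:
            fh.write("phylum\tquery\ttarget\tbits\tevalue\tstatus\n")
            for h in filtered:
                sc = "None" if h.score is None else f"{h.score:.2f}"
                ev = "None" if h.evalue is None else f"{h.evalue:.3g}"
                fh.write(f"{h.phylum}\t{h.query}\t{h.target}\t{sc}\t{ev}\t{h.status}\n")
        dom_mod.write_annotations_tsv(annotations.values(), outdir / "annotations.tsv")

    _stage(manifest, outdir, "filter", cfg_key, ["filtered_hits.tsv"], do_filter)
    if not wanted("orthology"):
        return finish()
    orthology_needed = _needs(
        manifest, outdir, "orthology", cfg_key, ["conservation.tsv", "intersection.tsv"]
    )
    if "filtered" not in state and orthology_needed:
        if "search" not in state:
            state["search"] = search_reference(bench, state["hmms"], config)
        filtered, _ = domain_filter_stage(
            bench, state["search"], state["domain_profiles"], config
        )
        state["filtered"] = filtered

    def do_orthology():
        conservation, common, reasons, _ = orthology_stage(bench, state["filtered"], config)
        conservation.to_tsv(outdir / "conservation.tsv")
        with open(outdir / "intersection.tsv", "w") as fh:
            fh.write("locus\tcommon\treason\n")
            for locus in sorted(common):
                fh.write(f"{locus}\t1\t\n")
            for locus, why in sorted(reasons.items()):
                fh.write(f"{locus}\t0\t{why}\n")
        state["common"] = common

    _stage(manifest, outdir, "orthology", cfg_key, ["conservation.tsv", "intersection.tsv"], do_orthology)
    if not wanted("promoters"):
        return finish()

    def do_promoters():
        regions, matches = promoter_stage(bench, config)
        prom_mod.write_matches_tsv(matches, outdir / "motif_matches.tsv")
        prom_mod.write_matches_bed(matches, regions, outdir / "motif_matches.bed")

    _stage(manifest, outdir, "promoters", cfg_key, ["motif_matches.tsv"], do_promoters)
    if not wanted("tree"):
        return finish()

    def do_tree():
        concat, tree = tree_stage(bench, config, seed=config.seed + 3)
        concat.to_fasta(outdir / "concatemer.afa")
        (outdir / "concatemer.nwk").write_text(phylo_mod.write_newick(tree) + "\n")

    _stage(manifest, outdir, "tree", cfg_key, ["concatemer.nwk"], do_tree)
    return finish()


# ---------------------------------------------------------------------------
# Reports in the published table layouts
# ---------------------------------------------------------------------------


def format_evalue(e) -> str:
    """Scientific notation, 2 decimals, uppercase E (e.g. 2.10E-30)."""
    if e is None or e == "None":
        return "None"
    e = float(e)
    if e == 0:
        return "0"
    return f"{e:.2E}"


def render_best_hit_row(organism, protein, function, target, common_name, evalue, flagged=False):
    hit = "None" if target is None else (f"{target} ({common_name})" if common_name else target)
    if flagged and target is not None:
        hit = f"**{hit}**"
    return f"{organism}\t{protein}\t{function}\t{hit}\t{format_evalue(evalue)}"


def render_reports(run_dir) -> list:
    """Format the stage outputs as published-style report tables."""
    run_dir = Path(run_dir)
    missing = [
        f for f in ("filtered_hits.tsv", "conservation.tsv", "motif_matches.tsv")
        if not (run_dir / f).exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing stage outputs: {', '.join(missing)}")
    import pandas as pd

    written = []

    hits = pd.read_csv(run_dir / "filtered_hits.tsv", sep="\t", keep_default_na=False)
    lines = ["Organism\tProtein\tClock function\tBest hit\tE value"]
    for _, r in hits.iterrows():
        target = None if r["target"] in ("None", "") else r["target"]
        ev = None if r["evalue"] in ("None", "") else r["evalue"]
        lines.append(
            render_best_hit_row(
                r["phylum"], r["query"], "clock analog", target, "", ev,
                flagged=r["status"] == "flagged",
            )
        )
    p = run_dir / "report_best_hits.tsv"
    p.write_text("\n".join(lines) + "\n")
    written.append(p)

    cons = pd.read_csv(run_dir / "conservation.tsv", sep="\t", keep_default_na=False)
    p = run_dir / "report_conservation.tsv"
    cons.to_csv(p, sep="\t", index=False)
    written.append(p)

    motifs = pd.read_csv(run_dir / "motif_matches.tsv", sep="\t", comment="#", keep_default_na=False)
    counts = motifs.groupby(["gene", "motif"]).size().unstack(fill_value=0)
    p = run_dir / "report_motif_occurrences.tsv"
    counts.to_csv(p, sep="\t")
    written.append(p)
    return written
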