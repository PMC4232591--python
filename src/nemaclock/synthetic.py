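"""Synthetic proteomes, seed ortholog sets, genomes and annotations with
planted ground truth.

The generator emulates the inputs of a multi-species clock-protein homolog
search without any download: protein families with a fixed domain
architecture evolve over a species tree by an i.i.d. per-site substitution
process (probability ``1 - exp(-b)`` of substituting to a uniformly chosen
different residue on a branch of length ``b``); indels are confined to the
inter-domain linkers, so domain-coordinate truth stays well defined.
Unrelated decoy proteins are i.i.d. background residues.  Small genomes carry
promoter windows with planted IUPAC cis-elements; accidental motif matches in
the background are scrubbed away so planted counts are exact.

For two leaves on branches ``b1, b2`` from a common ancestor the expected
per-site difference proportion of this process has the closed form

    P_diff = 1 - [(1-p1)(1-p2) + p1*p2/19],   p_i = 1 - exp(-b_i)

(two substituted sites coincide with probability 1/19).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import AA_ALPHABET
from .phylo import TreeNode
from .promoters import CLOCK_MOTIFS, IUPAC_SETS, MotifDef, revcomp, scan

N_AA = len(AA_ALPHABET)
DNA = "ACGT"


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Domain and family specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainSpec:
    id: str
    length: int
    consensus: str
    divergence: float = 0.05  # expected substitutions/site when instantiated

    def __post_init__(self):
        if self.length < 5:
            raise ValueError(f"domain {self.id}: length must be >= 5")
        if len(self.consensus) != self.length:
            raise ValueError(f"domain {self.id}: consensus length mismatch")
        if any(c not in AA_ALPHABET for c in self.consensus):
            raise ValueError(f"domain {self.id}: consensus has non-canonical residues")


@dataclass
class FamilySpec:
    id: str
    architecture: list  # ordered DomainSpec objects
    linker_length_range: tuple = (8, 20)
    species_tree: TreeNode | None = None

    def __post_init__(self):
        if not self.architecture:
            raise ValueError(f"family {self.id}: architecture must be non-empty")

    @property
    def domain_ids(self):
        return [d.id for d in self.architecture]


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated benchmark."""

    proteins: dict = field(default_factory=dict)  # family -> species -> protein id
    domain_coords: dict = field(default_factory=dict)  # protein id -> [(domain, start, end)]
    motif_plants: dict = field(default_factory=dict)  # gene -> [(motif, position, strand, word)]
    decoys: set = field(default_factory=set)


# ---------------------------------------------------------------------------
# Domain library
# ---------------------------------------------------------------------------


def _global_identity(a: str, b: str) -> float:
    from .align import align_global, blosum62

    aln = align_global(a, b, blosum62())
    same = sum(1 for x, y in zip(aln.aligned_a, aln.aligned_b) if x == y and x != "-")
    return same / len(aln.aligned_a)


def make_domain_library(
    n_domains: int,
    length_range: tuple = (25, 45),
    seed: int = 0,
    max_identity: float = 0.4,
    max_tries: int = 200,
) -> list:
    """Random domain consensus sequences with pairwise identity < 40%."""
    if n_domains < 1:
        raise ValueError("n_domains must be >= 1")
    lo, hi = length_range
    if lo < 5:
        raise ValueError("domains shorter than 5 residues are not allowed")
    rng = _rng(seed)
    out = []
    for i in range(n_domains):
        for attempt in range(max_tries):
            length = int(rng.integers(lo, hi + 1))
            cons = "".join(AA_ALPHABET[c] for c in rng.integers(0, N_AA, size=length))
            if all(_global_identity(cons, d.consensus) < max_identity for d in out):
                out.append(DomainSpec(f"dom{i:02d}", length, cons))
                break
        else:
            raise ValueError(
                f"could not draw domain {i} with pairwise identity < {max_identity} "
                f"after {max_tries} tries (constraint too tight for alphabet/length)"
            )
    return out


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------


def substitute(codes: np.ndarray, branch_length: float, rng) -> np.ndarray:
    """Per-site substitution: prob 1-exp(-b) of a uniform different residue."""
    if branch_length < 0:
        raise ValueError("branch lengths must be >= 0")
    if branch_length == 0 or len(codes) == 0:
        return codes.copy()
    p = 1.0 - np.exp(-branch_length)
    hit = rng.random(len(codes)) < p
    shifts = rng.integers(1, N_AA, size=len(codes))
    out = codes.copy()
    out[hit] = (out[hit] + shifts[hit]) % N_AA
    return out


def expected_difference(b1: float, b2: float) -> float:
    """Closed-form expected per-site difference between two leaves."""
    p1, p2 = 1.0 - np.exp(-b1), 1.0 - np.exp(-b2)
    return 1.0 - ((1 - p1) * (1 - p2) + p1 * p2 / (N_AA - 1))


def _encode(seq: str) -> np.ndarray:
    return np.array([AA_ALPHABET.index(c) for c in seq], dtype=np.int64)


def _decode(codes: np.ndarray) -> str:
    return "".join(AA_ALPHABET[c] for c in codes)


def _jitter_linker(codes: np.ndarray, length_range: tuple, rng) -> np.ndarray:
    """Indels inside a linker: redraw the length within range."""
    lo, hi = length_range
    target = int(rng.integers(lo, hi + 1))
    cur = len(codes)
    if target > cur:
        ins_pos = np.sort(rng.integers(0, cur + 1, size=target - cur))
        new = list(codes)
        for off, pos in enumerate(ins_pos):
            new.insert(pos + off, int(rng.integers(0, N_AA)))
        return np.array(new, dtype=np.int64)
    if target < cur:
        drop = set(rng.choice(cur, size=cur - target, replace=False).tolist())
        return np.array([c for k, c in enumerate(codes) if k not in drop], dtype=np.int64)
    return codes.copy()


def evolve_family(family: FamilySpec, seed: int = 0):
    """Evolve one family over its species tree.

    Returns ``(proteins, coords)`` where ``proteins`` maps species ->
    ``(protein_id, sequence)`` and ``coords`` maps protein id ->
    ``[(domain_id, start, end)]`` (0-based half-open).  One protein per leaf;
    domain order is preserved; zero-length branches reproduce the ancestor
    exactly.
    """
    tree = family.species_tree
    if tree is None or len(tree.leaves()) < 2:
        raise ValueError(f"family {family.id}: species tree must have >= 2 leaves")
    for node in tree.preorder():
        if node.length < 0:
            raise ValueError(f"family {family.id}: negative branch length")
    rng = _rng(seed)

    # ancestor: instantiated domains with per-domain divergence, random linkers
    segments = []  # (kind, domain_id, codes)
    lo, hi = family.linker_length_range
    segments.append(("linker", None, rng.integers(0, N_AA, size=int(rng.integers(lo, hi + 1)))))
    for dom in family.architecture:
        codes = substitute(_encode(dom.consensus), dom.divergence, rng)
        segments.append(("domain", dom.id, codes))
        segments.append(("linker", None, rng.integers(0, N_AA, size=int(rng.integers(lo, hi + 1)))))

    proteins = {}
    coords = {}

    def descend(node, segs):
        evolved = []
        for kind, did, codes in segs:
            new = substitute(np.asarray(codes, dtype=np.int64), node.length, rng)
            if kind == "linker" and node.length > 0:
                new = _jitter_linker(new, family.linker_length_range, rng)
            evolved.append((kind, did, new))
        if node.is_leaf():
            pid = f"{node.name}_{family.id}"
            pos = 0
            clist = []
            parts = []
            for kind, did, codes in evolved:
                if kind == "domain":
                    clist.append((did, pos, pos + len(codes)))
                pos += len(codes)
                parts.append(_decode(codes))
            proteins[node.name] = (pid, "".join(parts))
            coords[pid] = clist
        else:
            for child in node.children:
                descend(child, evolved)

    # the root's own length is ignored: the ancestor sits at the root
    root = TreeNode(children=tree.children if tree.children else [tree])
    for child in root.children:
        descend(child, segments)
    return proteins, coords


# ---------------------------------------------------------------------------
# Proteomes
# ---------------------------------------------------------------------------


def make_decoys(species: str, n_decoys: int, length_range=(100, 300), seed=0, background=None):
    rng = _rng(seed)
    bg = np.full(N_AA, 1.0 / N_AA) if background is None else np.asarray(background)
    out = []
    for i in range(n_decoys):
        ln = int(rng.integers(length_range[0], length_range[1] + 1))
        codes = rng.choice(N_AA, size=ln, p=bg)
        out.append((f"{species}_dec{i:04d}", _decode(codes)))
    return out


def make_proteome(
    species: str,
    family_proteins: dict,
    n_decoys: int = 500,
    decoy_length_range=(100, 300),
    seed: int = 0,
    background=None,
):
    """Assemble one species proteome: planted family members plus decoys.

    ``family_proteins`` maps family id -> (protein_id, sequence) for this
    species.  Returns ``(records, decoy_ids)``; record count is planted +
    ``n_decoys`` and ids are unique.
    """
    records = [family_proteins[f] for f in sorted(family_proteins)]
    decoys = make_decoys(species, n_decoys, decoy_length_range, seed, background)
    records = records + decoys
    ids = [i for i, _ in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate protein ids in proteome {species!r}")
    return records, {i for i, _ in decoys}


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for pid, seq in records:
            fh.write(f">{pid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Genomes with planted promoter elements
# ---------------------------------------------------------------------------


_MOTIF_BY_NAME = {m.name: m for m in CLOCK_MOTIFS}


def _concrete_word(pattern: str, rng) -> str:
    """A concrete word from the pattern's product set.

    Self-reverse-complementary words are redrawn when possible so a planted
    occurrence does not mirror itself on the minus strand.
    """
    for _ in range(10):
        word = "".join(
            IUPAC_SETS[c][int(rng.integers(0, len(IUPAC_SETS[c])))] for c in pattern
        )
        if word != revcomp(word):
            return word
    return word


def make_genome_with_promoters(
    genes,
    motif_plants,
    upstream_len: int = 3000,
    seed: int = 0,
    motifs=CLOCK_MOTIFS,
    cds_body_codons: int = 20,
    max_scrub_rounds: int = 200,
):
    """A small genome whose promoter windows contain exactly the planted motifs.

    ``genes`` is a list of ``(gene_id, strand)``; ``motif_plants`` a list of
    ``(gene_id, motif_name, offset, strand)`` with the offset relative to the
    ATG (-1 = adjacent base).  Background bases are i.i.d. uniform; any
    accidental motif match outside the planted footprints is re-randomized
    away, so after scrubbing every match of any catalog motif lies inside a
    planted footprint.

    Returns ``(genome, gff_text, truth)`` where genome maps contig ->
    sequence and truth maps gene -> list of ``(motif, position, strand,
    word)``.
    """
    rng = _rng(seed)
    genes = list(genes)
    gene_strand = dict(genes)
    if len(gene_strand) != len(genes):
        raise ValueError("duplicate gene ids")
    plants_by_gene = {g: [] for g, _ in genes}
    for gene, mname, offset, strand in motif_plants:
        if gene not in plants_by_gene:
            raise ValueError(f"plant references unknown gene {gene!r}")
        motif = _MOTIF_BY_NAME[mname] if isinstance(mname, str) else mname
        k = len(motif.pattern)
        if not (-upstream_len <= offset <= -k):
            raise ValueError(
                f"offset {offset} for {motif.name} on {gene} outside the "
                f"{upstream_len} bp window"
            )
        if motif.is_palindromic:
            strand = "+"  # palindromic patterns are reported on the plus strand
        plants_by_gene[gene].append((motif, offset, strand))

    truth = {}
    windows = {}
    for gene, _ in genes:
        window = list("".join(DNA[b] for b in rng.integers(0, 4, size=upstream_len)))
        footprints = []
        planted_keys = set()
        placed = []
        for motif, offset, strand in plants_by_gene[gene]:
            k = len(motif.pattern)
            j = offset + upstream_len
            if any(j < fe and j + k > fs for fs, fe in footprints):
                raise ValueError(f"overlapping plants on gene {gene!r}")
            word = _concrete_word(motif.pattern, rng)
            ins = word if strand == "+" else revcomp(word)
            window[j : j + k] = list(ins)
            footprints.append((j, j + k))
            planted_keys.add((motif.name, offset, strand))
            placed.append((motif.name, offset, strand, word))
        # scrub accidental matches outside planted footprints
        for _ in range(max_scrub_rounds):
            seq = "".join(window)
            dirty = []
            for m in scan(seq, motifs, both_strands=True, dedup_palindromes=False, gene=gene):
                j = m.position + upstream_len
                k = len(m.matched)
                inside = any(j >= fs and j + k <= fe for fs, fe in footprints)
                if not inside:
                    dirty.append((j, k))
            if not dirty:
                break
            for j, k in dirty:
                free = [
                    q
                    for q in range(j, j + k)
                    if not any(fs <= q < fe for fs, fe in footprints)
                ]
                if not free:
                    raise RuntimeError(
                        f"accidental match on {gene!r} lies fully inside planted "
                        "footprints and cannot be scrubbed"
                    )
                q = free[int(rng.integers(0, len(free)))]
                old = window[q]
                choices = [b for b in DNA if b != old]
                window[q] = choices[int(rng.integers(0, 3))]
        else:
            raise RuntimeError(f"scrubbing did not converge for gene {gene!r}")
        windows[gene] = "".join(window)
        truth[gene] = placed

    # assemble one contig; upstream windows laid down so extraction recovers them
    parts = []
    gff = ["##gff-version 3"]
    pos = 0  # 0-based running coordinate

    def spacer():
        nonlocal pos
        s = "".join(DNA[b] for b in rng.integers(0, 4, size=25))
        parts.append(s)
        pos += len(s)

    for gene, strand in genes:
        spacer()
        body = "".join(DNA[b] for b in rng.integers(0, 4, size=3 * cds_body_codons))
        cds = "ATG" + body + "TAA"
        if strand == "+":
            parts.append(windows[gene])
            pos += upstream_len
            cds_start0 = pos
            parts.append(cds)
            pos += len(cds)
            gff.append(
                f"chr1\tnemaclock\tgene\t{cds_start0 + 1}\t{pos}\t.\t+\t.\tID={gene}"
            )
            gff.append(
                f"chr1\tnemaclock\tCDS\t{cds_start0 + 1}\t{pos}\t.\t+\t0\t"
                f"ID={gene}.cds;Parent={gene}"
            )
        else:
            cds_start0 = pos
            parts.append(revcomp(cds))
            pos += len(cds)
            gff.append(
                f"chr1\tnemaclock\tgene\t{cds_start0 + 1}\t{pos}\t.\t-\t.\tID={gene}"
            )
            gff.append(
                f"chr1\tnemaclock\tCDS\t{cds_start0 + 1}\t{pos}\t.\t-\t0\t"
                f"ID={gene}.cds;Parent={gene}"
            )
            parts.append(revcomp(windows[gene]))
            pos += upstream_len
    spacer()
    genome = {"chr1": "".join(parts)}
    return genome, "\n".join(gff) + "\n", truth


# ---------------------------------------------------------------------------
# Standard benchmarks
# ---------------------------------------------------------------------------


def star_tree(labels, branch_length: float) -> TreeNode:
    return TreeNode(children=[TreeNode(name=l, length=branch_length) for l in labels])


def clade_tree(clades: dict, stem: float, leaf_branch: float) -> TreeNode:
    """Rooted tree: one stem per clade, equal leaf branches below it."""
    kids = []
    for _, labels in sorted(clades.items()):
        kids.append(
            TreeNode(
                length=stem,
                children=[TreeNode(name=l, length=leaf_branch) for l in labels],
            )
        )
    return TreeNode(children=kids)


@dataclass
class Benchmark:
    """The standard planted-truth study design.

    Ten domain-architecture families shared by 13 nematode-like species (the
    first is the reference), each proteome padded with unrelated decoys.  Six
    families also have seed-ortholog sets in both query phyla (insect-like
    and mammal-like), two in one phylum only each; the planted "common" set
    is therefore the six shared families.
    """

    species: list
    reference: str
    proteomes: dict  # species -> [(id, seq)]
    seed_sets: dict  # phylum -> {family: [(id, seq)]}
    families: list  # FamilySpec
    truth: SyntheticTruth
    insect_families: set
    mammal_families: set
    common_families: set
    domain_library: list
    genome: dict | None = None
    gff_text: str | None = None

    def proteome_db(self, species):
        from .orthology import ProteomeDB

        return ProteomeDB(species, self.proteomes[species])

    def architecture(self, family_id) -> list:
        for f in self.families:
            if f.id == family_id:
                return f.domain_ids
        raise KeyError(family_id)


def make_benchmark(
    n_families: int = 10,
    n_species: int = 13,
    n_decoys: int = 500,
    n_seed_taxa: int = 5,
    seed: int = 0,
    nematode_branch: float = 0.18,
    query_branch: float = 0.12,
    stem: float = 0.05,
    decoy_length_range=(100, 300),
    with_genome: bool = True,
    upstream_len: int = 3000,
) -> Benchmark:
    """Generate the standard planted benchmark (defaults: 10 families x 13
    species x 500 decoys/species, all pairwise divergences <= 0.6 subst/site).
    """
    rng = _rng(seed)
    sub = lambda: int(rng.integers(0, 2**31))

    # every family carries two domains (clock-protein scale, ~150-200 aa),
    # with a disjoint domain pair per family so architectures are distinct
    lib = make_domain_library(2 * n_families, (30, 50), seed=sub())

    species = [f"nem{i:02d}" for i in range(n_species)]
    reference = species[0]
    insects = [f"ins{i}" for i in range(n_seed_taxa)]
    mammals = [f"mam{i}" for i in range(n_seed_taxa)]

    fam_ids = [f"fam{i:02d}" for i in range(n_families)]
    n_common = max(1, n_families - 4)
    common = set(fam_ids[:n_common])
    insect_only = set(fam_ids[n_common : n_common + (n_families - n_common) // 2])
    mammal_only = set(fam_ids[n_common + len(insect_only) :])
    insect_fams = common | insect_only
    mammal_fams = common | mammal_only

    families = []
    truth = SyntheticTruth()
    per_species = {sp: {} for sp in species}
    seed_sets = {"insect": {}, "mammal": {}}

    for i, fid in enumerate(fam_ids):
        arch = [lib[2 * i], lib[2 * i + 1]]
        clades = {"a_nematoda": species}
        if fid in insect_fams:
            clades["b_insecta"] = insects
        if fid in mammal_fams:
            clades["c_mammalia"] = mammals
        tree = clade_tree(clades, stem=stem, leaf_branch=nematode_branch)
        # query clades get their own leaf branch length
        for kid in tree.children:
            names = set(c.name for c in kid.children)
            if not names & set(species):
                for c in kid.children:
                    c.length = query_branch
        fam = FamilySpec(fid, arch, (8, 20), tree)
        families.append(fam)
        proteins, coords = evolve_family(fam, seed=sub())
        truth.domain_coords.update(coords)
        truth.proteins[fid] = {}
        for sp in species:
            pid, pseq = proteins[sp]
            per_species[sp][fid] = (pid, pseq)
            truth.proteins[fid][sp] = pid
        if fid in insect_fams:
            seed_sets["insect"][fid] = [proteins[t] for t in insects]
        if fid in mammal_fams:
            seed_sets["mammal"][fid] = [proteins[t] for t in mammals]

    proteomes = {}
    for sp in species:
        records, decoy_ids = make_proteome(
            sp, per_species[sp], n_decoys, decoy_length_range, seed=sub()
        )
        proteomes[sp] = records
        truth.decoys |= decoy_ids

    genome = gff_text = None
    if with_genome:
        motif_cycle = [m.name for m in CLOCK_MOTIFS]
        genes = []
        plants = []
        for i, fid in enumerate(fam_ids):
            gene = truth.proteins[fid][reference]
            strand = "+" if i % 2 == 0 else "-"
            genes.append((gene, strand))
            mname = motif_cycle[i % len(motif_cycle)]
            offset = -(120 + (173 * i) % (upstream_len - 150))
            plants.append((gene, mname, offset, "+" if i % 3 else "-"))
        genome, gff_text, motif_truth = make_genome_with_promoters(
            genes, plants, upstream_len=upstream_len, seed=sub()
        )
        truth.motif_plants = motif_truth

    return Benchmark(
        species=species,
        reference=reference,
        proteomes=proteomes,
        seed_sets=seed_sets,
        families=families,
        truth=truth,
        insect_families=insect_fams,
        mammal_families=mammal_fams,
        common_families=common,
        domain_library=lib,
        genome=genome,
        gff_text=gff_text,
    )


def make_three_clade_families(
    n_clades: int = 3,
    per_clade: int = 4,
    n_families: int = 7,
    seed: int = 0,
    stem: float = 0.45,
    leaf_branch: float = 0.08,
):
    """Family sequence sets over a deep 3-clade species tree (one clade per
    phylum), for the concatemer phylogeny study.

    Returns ``(family_seqs, clades)`` where family_seqs maps family ->
    species -> sequence and clades maps clade name -> species list.
    """
    rng = _rng(seed)
    sub = lambda: int(rng.integers(0, 2**31))
    clades = {
        f"clade{c}": [f"c{c}s{s}" for s in range(per_clade)] for c in range(n_clades)
    }
    lib = make_domain_library(n_families, (30, 50), seed=sub())
    family_seqs = {}
    for i in range(n_families):
        fid = f"cfam{i:02d}"
        tree = clade_tree(clades, stem=stem, leaf_branch=leaf_branch)
        fam = FamilySpec(fid, [lib[i]], (6, 14), tree)
        proteins, _ = evolve_family(fam, seed=sub())
        family_seqs[fid] = {sp: seq for sp, (pid, seq) in proteins.items()}
    return family_seqs, clades
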