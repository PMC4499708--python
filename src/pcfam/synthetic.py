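"""Seeded generator of ground-truthed gene families.

Families evolve by a birth-death process along a fixed 10-taxon species
tree whose internal nodes carry the labels used for ancestral-count
reporting (V Viridiplantae, E Embryophyte, T Tracheophyte, A Angiosperm,
G Grass, Eu eudicots, R Rosid).  Every duplication (birth) is tagged
with a mechanism drawn from a tandem/segmental/retrotransposition mix;
retrocopies lose the conserved phase-1 intron, and the genome layout
realizes each mechanism geometrically (adjacent ordinals for tandem
copies, collinear anchor blocks for segmental copies, dispersed
intronless single-exon genes for retrocopies) so that the downstream
classifiers can be scored against exact truth.

Sequence divergence is produced by direct substitution placement, not a
continuous-time codon model: the emitted number of synonymous and
nonsynonymous changes is exact by construction, which makes target
recovery tests sharp.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .catalog_io import FeatureAnnotation, GeneModel, read_newick
from .kaks import STANDARD_CODE, CodonAlignment, ng86_sites

__all__ = [
    "DEFAULT_SPECIES_TREE",
    "SimulationConfig",
    "FamilyTruth",
    "simulate_family",
    "simulate_codon_pair",
    "simulate_genome_layout",
    "simulate_qpcr",
    "simulate_run",
]

#: Ten-taxon species tree with labelled ancestral nodes; branch lengths
#: are arbitrary fixed time units (ultrametric, depth 3).
DEFAULT_SPECIES_TREE = (
    "(Creinhardtii:3.0,(Ppatens:2.5,(Smoellendorffii:2.0,"
    "((Osativa:0.5,Zmays:0.5)G:1.0,"
    "(Slycopersicum:0.8,(Vvinifera:0.7,(Gmax:0.5,"
    "(Athaliana:0.3,Ptrichocarpa:0.3):0.2)R:0.2):0.1)Eu:0.7)A:0.5)"
    "T:0.5)E:0.5)V;"
)

#: Architecture-type frequencies used when fabricating feature tables;
#: chosen once as a plausible mix dominated by the full (I) and
#: GAS-less (II) architectures.
DEFAULT_TYPE_DISTRIBUTION = {
    "I": 0.30, "II": 0.25, "III": 0.05, "IV": 0.05, "V": 0.03,
    "VI": 0.10, "VII": 0.05, "VIII": 0.04, "IX": 0.10, "X": 0.03,
}

#: Feature tuple (has_sp, pcld_count, has_alr, has_gas) emitted for each
#: architecture type (the representative tuple of the decision table).
_TYPE_TO_TUPLE = {
    "I": (True, 1, True, True), "II": (True, 1, True, False),
    "III": (True, 2, True, True), "IV": (True, 2, True, False),
    "V": (True, 3, True, True), "VI": (True, 1, False, False),
    "VII": (True, 1, False, True), "VIII": (True, 2, False, False),
    "IX": (False, 1, False, False), "X": (False, 2, False, False),
}


@dataclass
class SimulationConfig:
    seed: int = 0
    species_tree: str = DEFAULT_SPECIES_TREE
    birth_rate: float = 0.25     # duplications / lineage / time unit
    loss_rate: float = 0.05      # losses / lineage / time unit
    p_tandem: float = 0.15
    p_segmental: float = 0.40
    p_retro: float = 0.45
    ks_per_time: float = 0.10    # synonymous subs / site / time unit / lineage
    n_codons: int = 300
    type_distribution: dict = field(
        default_factory=lambda: dict(DEFAULT_TYPE_DISTRIBUTION)
    )
    qpcr_noise_sd: float = 0.15
    max_intervening: int = 5     # tandem window the layout respects
    min_anchors: int = 3

    def __post_init__(self) -> None:
        if self.birth_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be nonnegative")
        total = self.p_tandem + self.p_segmental + self.p_retro
        if abs(total - 1) > 1e-9:
            raise ValueError("mechanism probabilities must sum to 1")
        if abs(sum(self.type_distribution.values()) - 1) > 1e-9:
            raise ValueError("type distribution must sum to 1")


@dataclass
class DuplicationEvent:
    mechanism: str
    branch: str          # species-tree branch (child-node key) it occurred on
    time_offset: float   # time from the top of that branch
    survived: bool
    node_id: int         # id of the duplication node in the gene tree


@dataclass
class FamilyTruth:
    events: list[DuplicationEvent]
    gene_species: dict[str, str]
    intron: dict[str, bool]
    arch_type: dict[str, str]
    true_ks: dict[frozenset, float]
    mechanism_pairs: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def n_duplications(self) -> int:
        return sum(e.survived for e in self.events)


def _species_key(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label or "|".join(
        sorted(lf.taxon.label for lf in node.leaf_iter())
    )


def simulate_family(
    config: SimulationConfig, max_attempts: int = 50
) -> tuple[dendropy.Tree, FamilyTruth]:
    """Birth-death simulation of one gene family along the species tree.

    Starts from a single intron-bearing gene at the root.  Returns the
    pruned gene tree (surviving lineages only; duplication nodes carry
    ``mechanism``) and the ground truth.  Families that go extinct, or
    leave fewer than two genes, are regenerated up to ``max_attempts``.
    """
    rng = np.random.default_rng(config.seed)
    sp_tree = read_newick(config.species_tree)
    for _ in range(max_attempts):
        result = _simulate_once(config, rng, sp_tree)
        if result is not None:
            return result
    raise RuntimeError(
        f"family extinct in {max_attempts} attempts; "
        "lower the loss rate or raise the birth rate"
    )


def _simulate_once(config, rng, sp_tree):
    b, d = config.birth_rate, config.loss_rate
    mechs = ["tandem", "segmental", "retrotransposition"]
    mech_p = [config.p_tandem, config.p_segmental, config.p_retro]
    events: list[DuplicationEvent] = []
    counters: dict[str, int] = {}
    node_seq = iter(range(10**9))

    def new_node():
        n = dendropy.Node()
        n.sim_id = next(node_seq)
        return n

    def at_species_node(sp_node, elapsed, intron):
        """Lineage arriving at species node sp_node; returns gene node."""
        if sp_node.is_leaf():
            sp = sp_node.taxon.label
            counters[sp] = counters.get(sp, 0) + 1
            leaf = new_node()
            leaf.gene_id = f"{sp}_g{counters[sp]}"
            leaf.intron = intron
            leaf.edge.length = elapsed
            return leaf
        subs = []
        for child in sp_node.child_nodes():
            sub = sim_branch(child, child.edge.length, intron)
            if sub is not None:
                subs.append(sub)
        if not subs:
            return None
        if len(subs) == 1:
            subs[0].edge.length += elapsed
            return subs[0]
        spec = new_node()
        spec.event = "speciation"
        for s in subs:
            spec.add_child(s)
        spec.edge.length = elapsed
        return spec

    def sim_branch(sp_child, t_left, intron):
        """One gene lineage on the branch into species node sp_child."""
        elapsed = 0.0
        while True:
            rate = b + d
            wait = rng.exponential(1 / rate) if rate > 0 else np.inf
            if wait >= t_left:
                return at_species_node(sp_child, t_left + elapsed, intron)
            elapsed += wait
            t_left -= wait
            if rng.random() < b / rate:  # duplication
                mech = mechs[rng.choice(3, p=mech_p)]
                child_intron = False if mech == "retrotransposition" else intron
                left = sim_branch(sp_child, t_left, intron)
                right = sim_branch(sp_child, t_left, child_intron)
                survived = left is not None and right is not None
                dup = new_node()
                events.append(
                    DuplicationEvent(
                        mechanism=mech,
                        branch=_species_key(sp_child),
                        time_offset=elapsed,
                        survived=survived,
                        node_id=dup.sim_id,
                    )
                )
                if not survived:
                    keep = left if left is not None else right
                    if keep is None:
                        return None
                    keep.edge.length += elapsed
                    return keep
                dup.event = "duplication"
                dup.mechanism = mech
                # the new copy is flagged so layout can place it
                right.is_new_copy = True
                dup.add_child(left)
                dup.add_child(right)
                dup.edge.length = elapsed
                return dup
            return None  # loss

    root_gene = at_species_node(sp_tree.seed_node, 0.0, intron=True)
    if root_gene is None:
        return None
    leaves = [n for n in root_gene.leaf_iter()]
    if len(leaves) < 2:
        return None

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root_gene
    for leaf in tree.leaf_node_iter():
        leaf.taxon = taxa.new_taxon(leaf.gene_id)
    tree.is_rooted = True

    gene_species = {
        leaf.taxon.label: leaf.taxon.label.rsplit("_g", 1)[0]
        for leaf in tree.leaf_node_iter()
    }
    intron = {leaf.taxon.label: leaf.intron for leaf in tree.leaf_node_iter()}

    labels = sorted(config.type_distribution)
    probs = [config.type_distribution[k] for k in labels]
    arch = {
        gid: labels[rng.choice(len(labels), p=probs)]
        for gid in sorted(gene_species)
    }

    pdm = tree.phylogenetic_distance_matrix()
    true_ks = {}
    taxa_list = sorted(tree.taxon_namespace, key=lambda t: t.label)
    for i, ta in enumerate(taxa_list):
        for tb in taxa_list[i + 1 :]:
            path_time = pdm.distance(ta, tb)
            true_ks[frozenset((ta.label, tb.label))] = (
                config.ks_per_time * path_time
            )

    truth = FamilyTruth(
        events=events,
        gene_species=gene_species,
        intron=intron,
        arch_type=arch,
        true_ks=true_ks,
    )
    return tree, truth


# ---------------------------------------------------------------------------
# codon pair simulation

_SENSE = [c for c, aa in STANDARD_CODE.items() if aa != "*"]
_BASES = "TCAG"


def _neighbors(codon):
    for pos in range(3):
        for base in _BASES:
            if base != codon[pos]:
                yield codon[:pos] + base + codon[pos + 1 :], pos


def _syn_neighbors(codon):
    aa = STANDARD_CODE[codon]
    return [n for n, _ in _neighbors(codon) if STANDARD_CODE[n] == aa]


def _nonsyn_neighbors(codon):
    aa = STANDARD_CODE[codon]
    return [
        n for n, _ in _neighbors(codon)
        if STANDARD_CODE[n] not in (aa, "*")
    ]


def simulate_codon_pair(
    target_ks: float,
    target_ratio: float = 0.3,
    n_codons: int = 300,
    seed: int = 0,
) -> tuple[CodonAlignment, dict]:
    """Emit a codon pair whose divergence targets the given Ks.

    The expected proportion of synonymous differences is the
    Jukes-Cantor inverse 3/4 (1 - e^{-4 Ks / 3}); Poisson-distributed
    synonymous and nonsynonymous changes are placed one per codon (so
    the realized difference counts are exact) and changes through stop
    codons never occur.  Returns the alignment and the realized truth
    (numbers of synonymous/nonsynonymous changes placed).
    """
    if target_ks < 0:
        raise ValueError("target Ks must be nonnegative")
    rng = np.random.default_rng(seed)
    ancestor = [
        _SENSE[i]
        for i in rng.choice(len(_SENSE), size=n_codons)
    ]
    # avoid terminal-stop ambiguity: keep every codon sense (guaranteed)
    s_sites = sum(ng86_sites(c)[0] for c in ancestor)
    n_sites = sum(ng86_sites(c)[1] for c in ancestor)
    p_s = 0.75 * (1 - np.exp(-4 * target_ks / 3))
    target_ka = target_ratio * target_ks
    p_n = 0.75 * (1 - np.exp(-4 * target_ka / 3))
    k_s = rng.poisson(p_s * s_sites) if target_ks > 0 else 0
    k_n = rng.poisson(p_n * n_sites) if target_ka > 0 else 0

    syn_ok = [i for i, c in enumerate(ancestor) if _syn_neighbors(c)]
    if k_s > len(syn_ok):
        raise ValueError(
            f"cannot place {k_s} synonymous changes on {len(syn_ok)} "
            "eligible codons; increase n_codons"
        )
    derived = list(ancestor)
    syn_idx = rng.choice(len(syn_ok), size=k_s, replace=False)
    used = set()
    for i in syn_idx:
        pos = syn_ok[i]
        options = _syn_neighbors(ancestor[pos])
        derived[pos] = options[rng.choice(len(options))]
        used.add(pos)
    nonsyn_ok = [
        i for i, c in enumerate(ancestor)
        if i not in used and _nonsyn_neighbors(c)
    ]
    if k_n > len(nonsyn_ok):
        raise ValueError(
            f"cannot place {k_n} nonsynonymous changes on "
            f"{len(nonsyn_ok)} free codons; increase n_codons"
        )
    non_idx = rng.choice(len(nonsyn_ok), size=k_n, replace=False)
    for i in non_idx:
        pos = nonsyn_ok[i]
        options = _nonsyn_neighbors(ancestor[pos])
        derived[pos] = options[rng.choice(len(options))]
    aln = CodonAlignment("".join(ancestor), "".join(derived))
    realized = {"syn_changes": int(k_s), "nonsyn_changes": int(k_n)}
    return aln, realized


# ---------------------------------------------------------------------------
# genome layout

def _gene_model_for(gid, species, chrom, ordinal, intron):
    start = ordinal * 1000
    if intron:
        # two exons, first coding segment 100 bp -> phase-1 intron at
        # residue 33.3, inside the default PCLD span (20, 120)
        exons = [(start, start + 99), (start + 200, start + 459)]
    else:
        exons = [(start, start + 359)]
    return GeneModel(
        gene_id=gid,
        species=species,
        chromosome=chrom,
        strand="+",
        start=exons[0][0],
        end=exons[-1][1],
        exons=exons,
    )


def simulate_genome_layout(
    tree: dendropy.Tree,
    truth: FamilyTruth,
    config: SimulationConfig,
):
    """Place every extant gene on chromosomes realizing its mechanism.

    Per species, the induced gene tree (restricted to that species'
    genes) branches only at duplication nodes; for each such node the
    leftmost descendant keeps its parent's location and the sibling
    clade's representative is placed by the event mechanism: tandem
    copies adjacent on the same chromosome, segmental copies on a fresh
    chromosome wrapped in a collinear block of ``min_anchors`` anchors,
    retrocopies far apart on a scatter chromosome as intronless
    single-exon genes.  Filler genes occupy every other ordinal.

    Returns ``(gene_models, features, anchors)`` where anchors are
    (chrom_a, ordinal_a, chrom_b, ordinal_b) tuples including both the
    family pairs and their filler companions.  Representative pairs per
    event are appended to ``truth.mechanism_pairs``.
    """
    rng = np.random.default_rng(config.seed + 101)
    species_leaves: dict[str, list] = {}
    for leaf in tree.leaf_node_iter():
        species_leaves.setdefault(
            truth.gene_species[leaf.taxon.label], []
        ).append(leaf.taxon.label)

    models: list[GeneModel] = []
    anchors: list[tuple[str, int, str, int]] = []
    truth.mechanism_pairs = []

    def induced_primary(node, wanted):
        """Leftmost leaf of node that belongs to the wanted species."""
        for leaf in node.leaf_iter():
            if leaf.taxon.label in wanted:
                return leaf.taxon.label
        return None

    for sp in sorted(species_leaves):
        wanted = set(species_leaves[sp])
        home = f"{sp}_c1"
        scatter = f"{sp}_r1"
        # chromosome contents: chrom -> ordered list of gene ids;
        # ordinal spacing applied at emission
        placements: dict[str, tuple[str, int]] = {}
        chrom_cursor: dict[str, int] = {}
        seg_count = 0

        def next_slot(chrom, step):
            cur = chrom_cursor.get(chrom, 10) + step
            chrom_cursor[chrom] = cur
            return cur

        def place_directives(node, anchor_gene):
            """Walk the induced tree; anchor_gene already placed."""
            nonlocal seg_count
            if node.is_leaf():
                return
            kids = [
                c for c in node.child_nodes()
                if induced_primary(c, wanted) is not None
            ]
            if len(kids) == 1:
                place_directives(kids[0], anchor_gene)
                return
            primary_child = kids[0]
            primary_gene = induced_primary(primary_child, wanted)
            place_directives(primary_child, anchor_gene)
            mech = getattr(node, "mechanism", "segmental")
            for other in kids[1:]:
                sec_gene = induced_primary(other, wanted)
                p_chrom, p_ord = placements[anchor_gene]
                if mech == "tandem":
                    # next free ordinal after the anchor; stacked tandem
                    # copies stay contiguous, so single linkage keeps the
                    # whole run in one cluster
                    offset = 1
                    while any(
                        loc == (p_chrom, p_ord + offset)
                        for loc in placements.values()
                    ):
                        offset += 1
                    placements[sec_gene] = (p_chrom, p_ord + offset)
                    chrom_cursor[p_chrom] = max(
                        chrom_cursor.get(p_chrom, 10), p_ord + offset
                    )
                elif mech == "segmental":
                    seg_count += 1
                    chrom = f"{sp}_s{seg_count}"
                    o = next_slot(chrom, 10)
                    placements[sec_gene] = (chrom, o)
                    for delta in range(
                        -(config.min_anchors // 2),
                        config.min_anchors - config.min_anchors // 2,
                    ):
                        anchors.append(
                            (p_chrom, p_ord + delta, chrom, o + delta)
                        )
                else:  # retrotransposition: dispersed, far apart
                    o = next_slot(scatter, 50)
                    placements[sec_gene] = (scatter, o)
                truth.mechanism_pairs.append((anchor_gene, sec_gene, mech))
                place_directives(other, sec_gene)

        root_gene = induced_primary(tree.seed_node, wanted)
        placements[root_gene] = (home, next_slot(home, 10))
        place_directives(tree.seed_node, root_gene)

        occupied: dict[str, dict[int, str]] = {}
        for gid, (chrom, o) in placements.items():
            occupied.setdefault(chrom, {})[o] = gid
        for chrom, slots in occupied.items():
            top = max(slots) + 5
            for o in range(1, top + 1):
                gid = slots.get(o)
                if gid is None:
                    models.append(
                        _gene_model_for(
                            f"{sp}_{chrom.rsplit('_', 1)[1]}_f{o}",
                            sp, chrom, o, intron=False,
                        )
                    )
                else:
                    models.append(
                        _gene_model_for(
                            gid, sp, chrom, o, intron=truth.intron[gid]
                        )
                    )

    from .catalog_io import _assign_ordinals

    _assign_ordinals(models)

    features = {}
    for gid, label in truth.arch_type.items():
        sp_flag, count, alr, gas = _TYPE_TO_TUPLE[label]
        features[gid] = FeatureAnnotation(
            gene_id=gid,
            has_sp=sp_flag,
            has_gas=gas,
            pcld_spans=[(20 + 110 * i, 120 + 110 * i) for i in range(count)],
            alr_spans=[(125, 145)] if alr else [],
        )
    return models, features, anchors


# ---------------------------------------------------------------------------
# qPCR

def simulate_qpcr(
    true_rq: dict[tuple[str, str], float],
    n_reps: int = 3,
    noise_sd: float = 0.15,
    seed: int = 0,
    ref_gene: str = "Actin1",
    calibrator: str = "CK",
    base_ct_ref: float = 20.0,
    base_dct: float = 4.0,
):
    """Fabricate a Ct table realizing the given relative expressions.

    ``true_rq`` maps (gene, condition) -> RQ relative to the calibrator
    condition; the calibrator itself always has RQ 1.  Each Ct value
    gets independent Gaussian noise of ``noise_sd`` cycles; with zero
    noise the Livak estimate returns the truth exactly.  Returns a
    pandas DataFrame with columns gene, condition, replicate, Ct.
    """
    import pandas as pd

    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    conditions = sorted({c for _, c in true_rq} | {calibrator})
    genes = sorted({g for g, _ in true_rq})
    rows = []
    for cond in conditions:
        for rep in range(1, n_reps + 1):
            rows.append(
                (ref_gene, cond, rep,
                 base_ct_ref + rng.normal(0, noise_sd) if noise_sd else base_ct_ref)
            )
    for gene in genes:
        for cond in conditions:
            rq = 1.0 if cond == calibrator else true_rq.get((gene, cond), 1.0)
            if rq <= 0:
                raise ValueError("true RQ must be positive")
            dct = base_dct - np.log2(rq)
            for rep in range(1, n_reps + 1):
                noise = rng.normal(0, noise_sd) if noise_sd else 0.0
                rows.append((gene, cond, rep, base_ct_ref + dct + noise))
    return pd.DataFrame(rows, columns=["gene", "condition", "replicate", "Ct"])


# ---------------------------------------------------------------------------
# run directory

def simulate_run(config: SimulationConfig, outdir) -> dict:
    """Simulate one family end to end and write its input files.

    Emits the species tree, gene tree, GFF3, feature table, per-pair
    codon alignments for the mechanism pairs, a qPCR Ct table and a
    JSON manifest holding the seed and the ground truth.
    """
    from . import catalog_io

    os.makedirs(outdir, exist_ok=True)
    tree, truth = simulate_family(config)
    models, features, anchors = simulate_genome_layout(tree, truth, config)

    sp_tree = read_newick(config.species_tree)
    catalog_io.write_newick(sp_tree, os.path.join(outdir, "species_tree.nwk"))
    catalog_io.write_newick(tree, os.path.join(outdir, "gene_tree.nwk"))
    catalog_io.write_gff3(models, os.path.join(outdir, "genes.gff3"))
    catalog_io.write_feature_table(
        features, os.path.join(outdir, "features.tsv")
    )
    with open(os.path.join(outdir, "anchors.tsv"), "w") as fh:
        fh.write("chrom_a\tordinal_a\tchrom_b\tordinal_b\n")
        for ca, oa, cb, ob in anchors:
            fh.write(f"{ca}\t{oa}\t{cb}\t{ob}\n")

    pair_dir = os.path.join(outdir, "pairs")
    os.makedirs(pair_dir, exist_ok=True)
    pair_files = []
    for i, (a, bgene, mech) in enumerate(truth.mechanism_pairs):
        ks = truth.true_ks[frozenset((a, bgene))]
        aln, realized = simulate_codon_pair(
            ks, n_codons=config.n_codons, seed=config.seed + 1000 + i
        )
        path = os.path.join(pair_dir, f"pair_{i:03d}.fasta")
        catalog_io.write_fasta(
            [
                catalog_io.SequenceRecord(a, aln.seq_a, "cds"),
                catalog_io.SequenceRecord(bgene, aln.seq_b, "cds"),
            ],
            path,
        )
        pair_files.append(
            {"file": os.path.basename(path), "genes": [a, bgene],
             "mechanism": mech, "true_ks": ks, **realized}
        )

    genes = sorted(truth.gene_species)[:9]
    rq = {}
    for g in genes:
        rq[(g, "salt")] = 0.25
        rq[(g, "drought")] = 0.5
    ct = simulate_qpcr(
        rq, n_reps=3, noise_sd=config.qpcr_noise_sd, seed=config.seed + 7
    )
    ct.to_csv(os.path.join(outdir, "qpcr.tsv"), sep="\t", index=False)

    manifest = {
        "seed": config.seed,
        "n_genes": len(truth.gene_species),
        "n_duplications": truth.n_duplications,
        "events": [
            {"mechanism": e.mechanism, "branch": e.branch,
             "time_offset": e.time_offset, "survived": e.survived}
            for e in truth.events
        ],
        "gene_species": truth.gene_species,
        "intron": truth.intron,
        "arch_type": truth.arch_type,
        "true_ks": {
            "|".join(sorted(k)): v for k, v in truth.true_ks.items()
        },
        "mechanism_pairs": truth.mechanism_pairs,
        "pair_alignments": pair_files,
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
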