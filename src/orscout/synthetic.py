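"""Seeded simulators for every input the pipeline consumes.

Every generator returns a ground-truth record alongside the artifact so
recovery tests (and the acceptance checks) compare pipeline output against
planted truth rather than against the pipeline itself.  All randomness flows
through an explicit seed; identical seeds give byte-identical outputs.

The simulated world: odorant-receptor-like single-exon genes of ~310 codons
carrying the family consensus motifs; orthologs planted in synthetic genome
contigs at controlled nucleotide identity and coverage; pseudogene lesions
(frameshift, premature stop, truncation); and 96-well reporter plates where
a receptor+odorant signal rides on basal and empty-vector background with
Gaussian well noise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .curation import DEFAULT_MOTIFS, Motif
from .seq import CODON_TO_AA, NucSeq, ProtSeq, STOP_CODONS, reverse_complement

BASES = "ACGT"
_NONSTOP_CODONS = sorted(c for c in CODON_TO_AA if c not in STOP_CODONS)
_AA_TO_CODONS: dict[str, list[str]] = {}
for _c in _NONSTOP_CODONS:
    _AA_TO_CODONS.setdefault(CODON_TO_AA[_c], []).append(_c)
AMINO_ACIDS = sorted(set(CODON_TO_AA.values()) - {"*"})

#: saturation of the planted effect size across the screening concentrations
POTENT_CONC_FACTOR = {10.0: 0.6, 100.0: 0.9, 1000.0: 1.0}
WEAK_CONC_FACTOR = {10.0: 0.0, 100.0: 0.5, 1000.0: 1.0}


@dataclass(frozen=True)
class PlantedGene:
    gene_id: str
    species: str
    contig_id: str
    position: int
    strand: str
    realized_identity_pct: float
    realized_coverage_pct: float
    lesion: str = "none"  # none | frameshift | premature_stop | truncation


@dataclass(frozen=True)
class AgonistTruth:
    or_name: str
    odorant: str
    is_true_agonist: bool
    true_potency_class: str  # 'potent' | 'weak' | 'none'
    effect_size_AU: float


@dataclass
class SyntheticTruth:
    seed: int
    params: dict = field(default_factory=dict)
    planted_genes: list = field(default_factory=list)  # list[PlantedGene]
    agonists: list = field(default_factory=list)  # list[AgonistTruth]

    def planted_table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(g) for g in self.planted_genes])

    def agonist_table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(a) for a in self.agonists])


# ---------------------------------------------------------------------------
# genes and genomes


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n)
    return [_NONSTOP_CODONS[i] for i in idx]


def simulate_or_gene(
    gene_id: str = "synOR1",
    length_codons: int = 310,
    motifs: Sequence[Motif] = DEFAULT_MOTIFS,
    seed: int = 0,
) -> NucSeq:
    """An OR-like gene: single ATG...stop ORF with the family motifs planted
    at canonical relative positions (~TM3, ~TM6, ~TM7), random non-stop
    codons elsewhere.  Default length 310 codons -> 930 nt including stop.
    """
    rng = np.random.default_rng(seed)
    n_internal = length_codons - 2  # minus start and stop codons
    # anchor positions as fractions of the protein, classic OR architecture
    anchors = [0.40, 0.76, 0.92]
    placements = []
    taken: set[int] = set()
    for motif, frac in zip(motifs, itertools.cycle(anchors)):
        start = int(frac * length_codons)
        start = min(start, n_internal - len(motif.pattern))
        if start < 1 or any(p in taken for p in range(start, start + len(motif.pattern))):
            raise ValueError("gene too short for the requested motif set")
        placements.append((start, motif.pattern))
        taken.update(range(start, start + len(motif.pattern)))
    codons = _random_codons(rng, n_internal)
    for start, pattern in placements:
        for off, aa in enumerate(pattern):
            choices = _AA_TO_CODONS[aa]
            codons[start - 1 + off] = choices[int(rng.integers(0, len(choices)))]
    residues = "ATG" + "".join(codons) + "TAA"
    return NucSeq(id=gene_id, residues=residues, description="simulated OR gene")


def mutate_to_identity(
    gene: NucSeq, target_identity_pct: float, seed: int = 0
) -> tuple[NucSeq, float]:
    """Substitute random positions until ungapped identity to the source hits
    the target (exact to the resolution of one site).  Returns the mutant and
    the realized identity."""
    if not (0 < target_identity_pct <= 100):
        raise ValueError("target identity must be in (0, 100]")
    rng = np.random.default_rng(seed)
    n = len(gene)
    n_sub = int(round(n * (1.0 - target_identity_pct / 100.0)))
    residues = list(gene.residues)
    if n_sub:
        positions = rng.choice(n, size=n_sub, replace=False)
        for p in positions:
            old = residues[p]
            alternatives = [b for b in BASES if b != old]
            residues[p] = alternatives[int(rng.integers(0, 3))]
    realized = 100.0 * (n - n_sub) / n
    return (
        NucSeq(id=gene.id, residues="".join(residues), description=gene.description),
        realized,
    )


def pseudogenize(gene: NucSeq, lesion: str, seed: int = 0) -> NucSeq:
    """Introduce a disabling lesion: 'frameshift' deletes one base mid-ORF,
    'premature_stop' writes a stop codon at ~40% of the ORF, 'truncation'
    keeps the first 60%."""
    rng = np.random.default_rng(seed)
    s = gene.residues
    if lesion == "frameshift":
        p = int(len(s) * 0.4) + int(rng.integers(0, 30))
        s = s[:p] + s[p + 1 :]
    elif lesion == "premature_stop":
        codon_i = (int(len(s) * 0.4) // 3) * 3
        s = s[:codon_i] + "TAA" + s[codon_i + 3 :]
    elif lesion == "truncation":
        s = s[: (int(len(s) * 0.6) // 3) * 3]
    else:
        raise ValueError(f"unknown lesion {lesion!r}")
    return NucSeq(id=gene.id, residues=s, description=f"{gene.description} [{lesion}]")


def simulate_genome(
    contig_id: str = "chrSyn", length: int = 20_000, seed: int = 0
) -> NucSeq:
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, 4, size=length)
    return NucSeq(
        id=contig_id,
        residues="".join(BASES[i] for i in idx),
        description="simulated contig",
    )


def plant_gene(
    genome: NucSeq,
    gene: NucSeq,
    coverage_fraction: float = 1.0,
    strand: str = "+",
    seed: int = 0,
    species: str = "synthetic",
    realized_identity_pct: float = 100.0,
) -> tuple[NucSeq, PlantedGene]:
    """Insert the first ``coverage_fraction`` of the gene into the genome at a
    random position (truncation models partial counterparts); reverse-
    complemented for strand '-'.  Truth records the realized coverage."""
    if not (0 < coverage_fraction <= 1.0):
        raise ValueError("coverage_fraction must be in (0, 1]")
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    rng = np.random.default_rng(seed)
    ins_len = int(round(coverage_fraction * len(gene)))
    fragment = gene.residues[:ins_len]
    if strand == "-":
        fragment = reverse_complement(fragment)
    pos = int(rng.integers(0, len(genome) + 1))
    residues = genome.residues[:pos] + fragment + genome.residues[pos:]
    truth = PlantedGene(
        gene_id=gene.id,
        species=species,
        contig_id=genome.id,
        position=pos,
        strand=strand,
        realized_identity_pct=realized_identity_pct,
        realized_coverage_pct=100.0 * ins_len / len(gene),
    )
    return NucSeq(id=genome.id, residues=residues, description=genome.description), truth


def simulate_lineage_cohort(
    categories: Mapping[str, str],
    seed: int = 0,
    shared_identity_pct: float = 85.0,
    contig_length: int = 20_000,
    species: Sequence[str] = ("chimpanzee", "dog", "mouse", "rat"),
) -> tuple[list[NucSeq], dict[str, list[NucSeq]], SyntheticTruth]:
    """A query cohort plus per-species genomes with orthologs planted
    according to ``categories`` (gene_id -> 'shared' | 'human_chimp_only' |
    'human_only').  Shared orthologs are planted in every genome,
    human+chimp ones in chimpanzee only, human-only ones nowhere."""
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(
        seed=seed,
        params=dict(shared_identity_pct=shared_identity_pct, contig_length=contig_length),
    )
    queries = []
    genomes: dict[str, list[NucSeq]] = {sp: [] for sp in species}
    for gi, (gene_id, category) in enumerate(sorted(categories.items())):
        gene = simulate_or_gene(gene_id, seed=int(rng.integers(0, 2**31)))
        queries.append(gene)
        if category == "human_only":
            targets: Sequence[str] = ()
        elif category == "human_chimp_only":
            targets = ("chimpanzee",)
        elif category == "shared":
            targets = tuple(species)
        else:
            raise ValueError(f"unknown category {category!r}")
        for sp in species:
            contig = simulate_genome(
                f"{sp}_ctg{gi}", contig_length, seed=int(rng.integers(0, 2**31))
            )
            if sp in targets:
                mutant, realized = mutate_to_identity(
                    gene, shared_identity_pct, seed=int(rng.integers(0, 2**31))
                )
                strand = "+" if rng.random() < 0.5 else "-"
                contig, planted = plant_gene(
                    contig,
                    mutant,
                    strand=strand,
                    seed=int(rng.integers(0, 2**31)),
                    species=sp,
                    realized_identity_pct=realized,
                )
                truth.planted_genes.append(planted)
            genomes[sp].append(contig)
    return queries, genomes, truth


def simulate_protein_family(
    n: int = 10,
    length: int = 310,
    substitution_rate: float = 0.2,
    seed: int = 0,
    prefix: str = "fam",
) -> list[ProtSeq]:
    """Star phylogeny: each leaf mutates each ancestral site independently
    with the given per-site probability (uniform replacement)."""
    rng = np.random.default_rng(seed)
    ancestor = rng.integers(0, len(AMINO_ACIDS), size=length)
    out = []
    for i in range(n):
        leaf = ancestor.copy()
        mutate = rng.random(length) < substitution_rate
        repl = rng.integers(0, len(AMINO_ACIDS) - 1, size=length)
        for j in np.nonzero(mutate)[0]:
            r = repl[j]
            leaf[j] = r if r < leaf[j] else r + 1  # uniform over the other 19
        out.append(
            ProtSeq(f"{prefix}{i}", "".join(AMINO_ACIDS[k] for k in leaf))
        )
    return out


def simulate_two_clade_family(
    n_per_clade: int = 4,
    length: int = 200,
    within_rate: float = 0.03,
    between_rate: float = 0.5,
    seed: int = 0,
) -> tuple[list[ProtSeq], set[frozenset]]:
    """Two well-separated clades; returns the sequences and the true clade
    split (as a bipartition over leaf names)."""
    rng = np.random.default_rng(seed)
    seqs = []
    for clade in range(2):
        anc = simulate_protein_family(
            1, length, between_rate if clade else 0.0, seed=int(rng.integers(0, 2**31))
        )[0]
        leaves = _descend(anc, n_per_clade, within_rate, rng, f"c{clade}_")
        seqs.extend(leaves)
    split = frozenset(s.id for s in seqs if s.id.startswith("c1_"))
    return seqs, {split}


def _descend(ancestor: ProtSeq, n: int, rate: float, rng, prefix: str) -> list[ProtSeq]:
    out = []
    arr = np.array([AMINO_ACIDS.index(a) for a in ancestor.residues])
    for i in range(n):
        leaf = arr.copy()
        mutate = rng.random(len(arr)) < rate
        repl = rng.integers(0, len(AMINO_ACIDS) - 1, size=len(arr))
        for j in np.nonzero(mutate)[0]:
            r = repl[j]
            leaf[j] = r if r < leaf[j] else r + 1
        out.append(ProtSeq(f"{prefix}{i}", "".join(AMINO_ACIDS[k] for k in leaf)))
    return out


def random_additive_tree_distances(
    n_taxa: int, seed: int = 0
) -> tuple[np.ndarray, list[str], str, set]:
    """A random binary tree with positive branch lengths and its exact
    (additive) leaf-to-leaf distance matrix.  Returns (distances, labels,
    newick string, non-trivial bipartitions of the generating tree); each
    bipartition is the frozenset of leaf labels on the side not containing
    labels[0]."""
    rng = np.random.default_rng(seed)
    labels = [f"t{i}" for i in range(n_taxa)]
    # random sequential joining into an unrooted binary tree
    nodes: list[dict] = [{"name": lb, "edges": {}} for lb in labels]
    # adjacency with branch lengths on a growing tree
    import collections

    adj: dict[int, list[tuple[int, float]]] = collections.defaultdict(list)
    next_id = n_taxa

    def blen() -> float:
        return float(rng.uniform(0.05, 1.0))

    # start with a star of the first three taxa
    center = next_id
    next_id += 1
    for i in range(3):
        w = blen()
        adj[center].append((i, w))
        adj[i].append((center, w))
    # attach remaining taxa by splitting a random existing edge
    for leaf in range(3, n_taxa):
        edges = [(u, v, w) for u in adj for v, w in adj[u] if u < v]
        u, v, w = edges[int(rng.integers(0, len(edges)))]
        mid = next_id
        next_id += 1
        adj[u] = [(x, wx) for x, wx in adj[u] if x != v] + [(mid, w / 2)]
        adj[v] = [(x, wx) for x, wx in adj[v] if x != u] + [(mid, w / 2)]
        adj[mid] = [(u, w / 2), (v, w / 2)]
        wl = blen()
        adj[mid].append((leaf, wl))
        adj[leaf].append((mid, wl))

    # all-pairs leaf distances by BFS
    dist = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in seen:
                    seen[v] = seen[u] + w
                    stack.append(v)
        for dst in range(n_taxa):
            dist[src, dst] = seen[dst]

    def to_newick(u: int, parent: int) -> str:
        kids = [(v, w) for v, w in adj[u] if v != parent]
        if not kids:
            return labels[u]
        return "(" + ",".join(f"{to_newick(v, u)}:{w:.6f}" for v, w in kids) + ")"

    newick = to_newick(center, -1) + ";"

    # true bipartitions: leaves on the far side of each internal edge
    def leaves_beyond(u: int, parent: int) -> set[int]:
        out = set()
        for v, _ in adj[u]:
            if v != parent:
                out |= leaves_beyond(v, u)
        if u < n_taxa:
            out.add(u)
        return out

    splits: set[frozenset] = set()
    for u in adj:
        for v, _ in adj[u]:
            if u < v:
                side = leaves_beyond(v, u)
                if 2 <= len(side) <= n_taxa - 2:
                    if 0 in side:
                        side = set(range(n_taxa)) - side
                    splits.add(frozenset(labels[i] for i in side))
    return dist, labels, newick, splits


# ---------------------------------------------------------------------------
# plates


def _well_label(i: int) -> str:
    return f"{'ABCDEFGH'[(i // 12) % 8]}{i % 12 + 1}"


def simulate_plate_dataset(
    or_names: Sequence[str],
    odorants: Sequence[str],
    agonist_truth: Mapping[tuple[str, str], tuple[str, float]],
    basal_AU: float = 1e5,
    empty_AU: float = 1e5,
    noise_sd_AU: float = 3e4,
    n_replicates: int = 2,
    seed: int = 0,
    gfp_fraction: float = 0.95,
    rho_tagged_states: Sequence[bool] = (False,),
    concentrations: Sequence[float] = (10.0, 100.0, 1000.0),
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Well-level fluorescence for a screen, one odorant per plate.

    ``agonist_truth`` maps (or_name, odorant) -> (potency, effect_AU) with
    potency 'potent' or 'weak'; unlisted pairs are non-agonists.  Each well
    reads condition mean + seeded Gaussian noise; agonist wells add the
    effect scaled by a saturating concentration factor (0.6/0.9/1.0 for
    potent, 0/0.5/1.0 for weak at 10/100/1000 uM).
    """
    if noise_sd_AU < 0:
        raise ValueError("noise_sd_AU must be >= 0")
    for key, (potency, effect) in agonist_truth.items():
        if effect < 0:
            raise ValueError(f"effect size for {key} must be >= 0")
        if potency not in ("potent", "weak"):
            raise ValueError(f"unknown potency {potency!r} for {key}")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(
        seed=seed,
        params=dict(
            basal_AU=basal_AU,
            empty_AU=empty_AU,
            noise_sd_AU=noise_sd_AU,
            n_replicates=n_replicates,
            gfp_fraction=gfp_fraction,
        ),
    )
    for orn in or_names:
        for od in odorants:
            potency, effect = agonist_truth.get((orn, od), ("none", 0.0))
            truth.agonists.append(
                AgonistTruth(orn, od, potency != "none", potency, effect)
            )

    rows = []
    for plate_i, odorant in enumerate(odorants):
        plate_id = f"plate{plate_i + 1:03d}"
        wi = 0

        def add_well(construct, or_name, tagged, od, conc, rep, fl, gfp=np.nan):
            nonlocal wi
            rows.append(
                (
                    plate_id,
                    _well_label(wi),
                    construct,
                    or_name,
                    tagged,
                    od,
                    conc,
                    rep,
                    fl,
                    gfp,
                )
            )
            wi += 1

        def noise() -> float:
            return float(rng.normal(0.0, noise_sd_AU)) if noise_sd_AU else 0.0

        for orn in or_names:
            potency, effect = agonist_truth.get((orn, odorant), ("none", 0.0))
            factors = POTENT_CONC_FACTOR if potency == "potent" else WEAK_CONC_FACTOR
            for tagged in rho_tagged_states:
                for conc in concentrations:
                    signal = effect * factors[conc] if potency != "none" else 0.0
                    for rep in range(1, n_replicates + 1):
                        add_well(
                            "or", orn, tagged, odorant, conc, rep,
                            basal_AU + signal + noise(),
                        )
                for rep in range(1, n_replicates + 1):
                    add_well("or", orn, tagged, None, 0.0, rep, basal_AU + noise())
        for conc in concentrations:
            for rep in range(1, n_replicates + 1):
                add_well("empty_vector", None, False, odorant, conc, rep, empty_AU + noise())
        for rep in range(1, n_replicates + 1):
            add_well("empty_vector", None, False, None, 0.0, rep, empty_AU + noise())
        for rep in range(1, 3):
            add_well("gfp_control", None, False, None, 0.0, rep, np.nan, gfp=gfp_fraction)

    wells = pd.DataFrame(
        rows,
        columns=[
            "plate_id",
            "well",
            "construct",
            "or_name",
            "rho_tagged",
            "odorant",
            "concentration_uM",
            "replicate",
            "fluorescence_AU",
            "gfp_fraction",
        ],
    )
    return wells, truth


def expected_potency_class(
    potency: str, effect_AU: float, threshold: float = 3e5
) -> str:
    """Noise-free measured potency class implied by a planted agonist: the
    lowest concentration whose saturated effect strictly exceeds the hit
    threshold."""
    if potency == "none":
        return "none"
    factors = POTENT_CONC_FACTOR if potency == "potent" else WEAK_CONC_FACTOR
    classes = {10.0: "high", 100.0: "mid", 1000.0: "low"}
    for conc in sorted(factors):
        if effect_AU * factors[conc] > threshold:
            return classes[conc]
    return "none"


def demo_agonist_truth(
    or_names: Sequence[str], odorants: Sequence[str]
) -> dict[tuple[str, str], tuple[str, float]]:
    """A screen-sized demo truth mixing potent and weak agonist pairs.

    With nine receptors and 37 odorants it plants five receptors carrying a
    potent (10-uM) agonist across nine odorants, plus weak pairs bringing
    the responding-odorant total to fourteen and giving every receptor at
    least one agonist — the qualitative structure of a small deorphanization
    screen.
    """
    if len(or_names) < 9 or len(odorants) < 14:
        raise ValueError("demo truth needs >= 9 receptors and >= 14 odorants")
    # potent effect = 3x the hit threshold so every concentration of a potent
    # pair clears the threshold by many noise SDs; weak pairs only at the top
    potent_effect, weak_effect = 9e5, 4.5e5
    truth: dict[tuple[str, str], tuple[str, float]] = {}
    # five potent receptors covering nine distinct odorants (2+2+2+2+1)
    potent_or = list(or_names[:5])
    k = 0
    for i, orn in enumerate(potent_or):
        n_od = 2 if i < 4 else 1
        for _ in range(n_od):
            truth[(orn, odorants[k])] = ("potent", potent_effect)
            k += 1
    # weak-only pairs on five further odorants, one per remaining receptor,
    # plus an extra weak pair so breadth varies
    weak_or = list(or_names[5:9])
    for j, orn in enumerate(weak_or):
        truth[(orn, odorants[9 + j])] = ("weak", weak_effect)
    truth[(or_names[0], odorants[13])] = ("weak", weak_effect)
    return truth
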