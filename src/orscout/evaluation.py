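"""Benchmark experiments that measure the pipeline against planted truth.

Each function simulates inputs with the package's generators, runs the
corresponding analysis stage, and scores the result against the generator's
truth record.  All randomness derives from the caller's seed.
"""

from __future__ import annotations

import numpy as np

from .align import AlignParams, seed_and_extend_align
from .curation import curate_family
from .homology import call_presence, summarize_best_hit
from .phylo import build_nj_tree, pairwise_identity_matrix
from .screen import hit_calls, response_table, summarize_screen
from .seq import NucSeq
from .synthetic import (
    demo_agonist_truth,
    expected_potency_class,
    mutate_to_identity,
    plant_gene,
    pseudogenize,
    random_additive_tree_distances,
    simulate_genome,
    simulate_or_gene,
    simulate_plate_dataset,
)


def _subseed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31))


def seeded_alignment_sw_agreement(
    seed: int, n_instances: int = 50, identity_range=(0.75, 0.95)
) -> dict:
    """Fraction of random planted-homology instances (query <= 300 nt,
    target <= 2 kb) on which the seeded aligner's top score equals the full
    Smith-Waterman optimum computed by an independent DP (Biopython)."""
    from Bio import Align

    from .seq import reverse_complement

    params = AlignParams(k=8, min_score=20)
    oracle = Align.PairwiseAligner()
    oracle.mode = "local"
    oracle.match_score = params.match
    oracle.mismatch_score = params.mismatch
    oracle.open_gap_score = params.gap_open
    oracle.extend_gap_score = params.gap_extend

    rng = np.random.default_rng(seed)
    bases = "ACGT"
    agree = 0
    for _ in range(n_instances):
        qlen = int(rng.integers(80, 300))
        tlen = int(rng.integers(800, 2000))
        q = "".join(bases[i] for i in rng.integers(0, 4, qlen))
        t = list(bases[i] for i in rng.integers(0, 4, tlen))
        seg = list(q)
        ident = float(rng.uniform(*identity_range))
        for pos in rng.choice(qlen, int(qlen * (1 - ident)), replace=False):
            seg[pos] = bases[int(rng.integers(0, 4))]
        ins = int(rng.integers(0, tlen - qlen))
        t[ins:ins] = seg
        t = "".join(t)
        hits = seed_and_extend_align(NucSeq("q", q), NucSeq("t", t), params)
        best = hits[0].score if hits else 0
        sw = max(oracle.score(q, t), oracle.score(reverse_complement(q), t))
        agree += best == sw
    return {"agreement_fraction": agree / n_instances, "n": n_instances}


def presence_call_recovery(seed: int, n_reps: int = 100) -> dict:
    """Planted-ortholog recovery at the 70/70 rule: per replicate, one
    ortholog mutated to ~80% identity (must be called present) and one to
    ~60% (must be called absent), both full coverage."""
    rng = np.random.default_rng(seed)
    correct = 0
    total = 0
    for _ in range(n_reps):
        gene = simulate_or_gene("q", seed=_subseed(rng))
        for target_identity, want_present in ((80.0, True), (60.0, False)):
            mutant, _ = mutate_to_identity(gene, target_identity, seed=_subseed(rng))
            genome = simulate_genome("ctg", 6000, seed=_subseed(rng))
            genome, _ = plant_gene(
                genome, mutant, strand="+" if rng.random() < 0.5 else "-",
                seed=_subseed(rng),
            )
            hits = seed_and_extend_align(gene, genome)
            ident, cov, _ = summarize_best_hit(hits, len(gene))
            got = call_presence("q", "mouse", ident, cov).present
            correct += got == want_present
            total += 1
    boundary = call_presence("q", "mouse", 70.0, 70.0).present
    return {
        "accuracy_fraction": correct / total,
        "boundary_70_70_present": bool(boundary),
        "n": total,
    }


def curation_recovery(seed: int, n_genes: int = 20, n_pseudo: int = 5) -> dict:
    """Exact functional/pseudogene recovery on a family with planted
    frameshift and premature-stop lesions, plus the 293-residue borderline
    case with and without a manual override."""
    rng = np.random.default_rng(seed)
    genes, truth = [], {}
    for i in range(n_genes):
        g = simulate_or_gene(f"fam{i:02d}", seed=_subseed(rng))
        if i < n_pseudo:
            g = pseudogenize(g, ["frameshift", "premature_stop"][i % 2], seed=_subseed(rng))
            truth[g.id] = "pseudogene"
        else:
            truth[g.id] = "functional"
        genes.append(g)
    decisions = curate_family(genes)
    n_correct = sum(decisions[gid].status == truth[gid] for gid in truth)

    borderline = NucSeq("borderline", "ATG" + "GCT" * 292 + "TAA")  # 293 aa + stop
    plain = curate_family([borderline])["borderline"]
    forced = curate_family(
        [borderline], overrides={"borderline": "intact ORF, all family motifs"}
    )["borderline"]
    return {
        "accuracy_fraction": n_correct / n_genes,
        "n": n_genes,
        "borderline_coding_nt": plain.coding_length_nt,
        "borderline_pseudogene_without_override": plain.status == "pseudogene",
        "borderline_functional_with_override": forced.status == "functional"
        and forced.overridden,
    }


def nj_topology_recovery(seed: int, n_instances: int = 200) -> dict:
    """Fraction of random 6-12-taxon additive-distance instances on which
    neighbor joining recovers the generating topology exactly (all true
    bipartitions, no false ones)."""
    rng = np.random.default_rng(seed)
    exact = 0
    for _ in range(n_instances):
        n = int(rng.integers(6, 13))
        d, labels, _, true_splits = random_additive_tree_distances(n, seed=_subseed(rng))
        tree = build_nj_tree(d, labels)
        exact += tree.bipartitions() == true_splits
    return {"recovery_fraction": exact / n_instances, "n": n_instances}


def plate_screen_performance(
    seed: int,
    n_screens: int = 200,
    n_ors: int = 9,
    n_odorants: int = 37,
    n_agonists: int = 5,
    effect_AU: float = 6e5,
    noise_sd_AU: float = 3e4,
) -> dict:
    """Hit sensitivity and per-cell false-hit rate over seeded screens with
    planted potent agonists, at the strict fixed-threshold rule."""
    rng = np.random.default_rng(seed)
    ors = [f"OR{i}" for i in range(1, n_ors + 1)]
    ods = [f"od{i:02d}" for i in range(1, n_odorants + 1)]
    tp = fn = fp = tn = 0
    for _ in range(n_screens):
        pairs = set()
        while len(pairs) < n_agonists:
            pairs.add(
                (ors[int(rng.integers(n_ors))], ods[int(rng.integers(n_odorants))])
            )
        truth_map = {p: ("potent", effect_AU) for p in pairs}
        wells, _ = simulate_plate_dataset(
            ors, ods, truth_map, noise_sd_AU=noise_sd_AU, seed=_subseed(rng)
        )
        resp, _ = response_table(wells)
        for c in hit_calls(resp):
            responded = c.potency_class != "none"
            if (c.or_name, c.odorant) in pairs:
                tp += responded
                fn += not responded
            else:
                fp += responded
                tn += not responded
    return {
        "sensitivity_fraction": tp / (tp + fn),
        "false_hit_fraction": fp / (fp + tn),
        "n_agonist_cells": tp + fn,
        "n_null_cells": fp + tn,
    }


def potency_matrix_recovery(
    seed: int, n_screens: int = 20, effect_AU: float = 9e5, noise_sd_AU: float = 3e4
) -> dict:
    """Fraction of screens whose measured potency matrix equals the planted
    truth exactly (effects 3x the hit threshold, noise a tenth of it)."""
    rng = np.random.default_rng(seed)
    ors = [f"OR{i}" for i in range(1, 10)]
    ods = [f"od{i:02d}" for i in range(1, 38)]
    exact = 0
    for _ in range(n_screens):
        # exact recovery needs every planted effect at 3x the threshold, so
        # the demo pair structure is re-planted at effect_AU throughout
        truth_map = {
            pair: (potency, effect_AU)
            for pair, (potency, _) in demo_agonist_truth(ors, ods).items()
        }
        wells, truth = simulate_plate_dataset(
            ors, ods, truth_map, noise_sd_AU=noise_sd_AU, seed=_subseed(rng)
        )
        resp, _ = response_table(wells)
        calls = {(c.or_name, c.odorant): c.potency_class for c in hit_calls(resp)}
        ok = all(
            calls[(a.or_name, a.odorant)]
            == expected_potency_class(a.true_potency_class, a.effect_size_AU)
            for a in truth.agonists
        )
        exact += ok
    return {"exact_fraction": exact / n_screens, "n": n_screens}


def demo_screen_counts(seed: int) -> dict:
    """Screen-level summary counts on the demo truth (9 receptors, 37
    odorants; 14 responding odorants, 9 at 10 uM, 5 potent receptors)."""
    ors = [f"OR{i}" for i in range(1, 10)]
    ods = [f"od{i:02d}" for i in range(1, 38)]
    truth_map = demo_agonist_truth(ors, ods)
    # effects in the demo truth are 3x threshold, so counts are noise-robust
    wells, _ = simulate_plate_dataset(ors, ods, truth_map, seed=seed)
    resp, _ = response_table(wells)
    s = summarize_screen(hit_calls(resp))
    return {
        "odorants_responding": s.n_odorants_responding,
        "odorants_at_10uM": s.n_odorants_hit_at_10uM,
        "receptors_at_10uM": s.n_ors_hit_at_10uM,
        "receptors_responding": s.n_ors_responding,
    }
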