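"""Presence calls, lineage classification, and the cohort screen."""

import numpy as np
import pytest

from orscout.align import AlignmentHit
from orscout.curation import curate_family
from orscout.homology import (
    SCREEN_SPECIES,
    call_presence,
    classify_lineage,
    run_lineage_screen,
    summarize_best_hit,
)
from orscout.seq import NucSeq


def _hit(score, matches, cols, q_span=(0, 100), t_start=0):
    return AlignmentHit(
        "q", "t", q_span[0], q_span[1], t_start, t_start + cols, "+", matches, cols, score
    )


def test_best_hit_summary_arithmetic():
    ident, cov, best = summarize_best_hit([_hit(80, 90, 100, q_span=(0, 100))], 120)
    assert ident == pytest.approx(90.0)
    assert cov == pytest.approx(100 * 100 / 120)


def test_no_hits_summarize_to_zero():
    assert summarize_best_hit([], 100)[:2] == (0.0, 0.0)


def test_best_hit_tie_breaking():
    a = _hit(50, 60, 100, t_start=500)
    b = _hit(50, 70, 100, t_start=900)  # same score, more matches: wins
    c = _hit(50, 70, 100, t_start=100)  # same score+matches, leftmost: wins
    assert summarize_best_hit([a, b, c], 100)[2] is c


@pytest.mark.parametrize(
    "identity,coverage,present",
    [
        (70.0, 70.0, True),  # inclusive boundary on both axes
        (69.9, 99.0, False),
        (95.0, 50.0, False),
        (100.0, 100.0, True),
    ],
)
def test_presence_thresholds_inclusive(identity, coverage, present):
    call = call_presence("q", "mouse", identity, coverage)
    assert call.present is present


def test_presence_threshold_validation():
    with pytest.raises(ValueError):
        call_presence("q", "mouse", 50, 50, id_threshold=101)


def test_presence_monotone_in_identity_and_coverage():
    rng = np.random.default_rng(9)
    for _ in range(200):
        i1, c1 = rng.uniform(0, 100, 2)
        i2 = min(100, i1 + rng.uniform(0, 30))
        c2 = min(100, c1 + rng.uniform(0, 30))
        p1 = call_presence("q", "rat", i1, c1).present
        p2 = call_presence("q", "rat", i2, c2).present
        assert p2 >= p1  # improving the hit never loses presence


def _calls(present_in):
    return {
        sp: call_presence("q", sp, 90.0 if sp in present_in else 10.0,
                          90.0 if sp in present_in else 10.0)
        for sp in SCREEN_SPECIES
    }


@pytest.mark.parametrize(
    "present_in,category",
    [
        ((), "human_only"),
        (("chimpanzee",), "human_chimp_only"),
        (("dog",), "shared"),
        (("chimpanzee", "mouse"), "shared"),
        (("chimpanzee", "dog", "mouse", "rat"), "shared"),
    ],
)
def test_lineage_categories(present_in, category):
    assert classify_lineage("q", _calls(present_in)).category == category


def test_lineage_requires_all_four_species():
    calls = _calls(())
    del calls["rat"]
    with pytest.raises(ValueError):
        classify_lineage("q", calls)


def test_cohort_screen_recovers_planted_lineages(lineage_cohort):
    queries, genomes, truth = lineage_cohort
    decisions = curate_family(queries)
    result = run_lineage_screen(queries, genomes, decisions)
    assert result.category_counts == {
        "shared": 8,
        "human_only": 1,
        "human_chimp_only": 1,
    }
    assert sorted(result.selected) == ["g08", "g09"]
    # measured identity of planted orthologs within 2 points of realized truth
    by_gene = {
        (g.gene_id, g.species): g for g in truth.planted_genes
    }
    for row in result.screen_table.itertuples():
        planted = by_gene.get((row.query_id, row.species))
        if planted is not None:
            assert abs(row.best_identity_pct - planted.realized_identity_pct) < 2.0
            assert row.best_coverage_pct >= 95.0
            assert row.present
        else:
            assert not row.present


def test_curated_pseudogene_excluded_from_selection(lineage_cohort):
    queries, genomes, _ = lineage_cohort
    from orscout.synthetic import pseudogenize

    # break the human-only gene with a frameshift before curation
    broken = [pseudogenize(q, "frameshift", seed=1) if q.id == "g08" else q
              for q in queries]
    decisions = curate_family(broken)
    assert decisions["g08"].status == "pseudogene"
    result = run_lineage_screen(broken, genomes, decisions)
    assert "g08" not in result.selected
    assert not set(result.selected) & {
        gid for gid, d in decisions.items() if not d.is_functional
    }


def test_empty_genome_set_rejected(lineage_cohort):
    queries, _, _ = lineage_cohort
    with pytest.raises(ValueError):
        run_lineage_screen(queries, {}, curate_family(queries))


def test_unreadable_genome_flags_queries_incomplete(lineage_cohort, tmp_path):
    queries, genomes, _ = lineage_cohort
    genomes = dict(genomes)
    genomes["rat"] = tmp_path / "missing.fasta"
    result = run_lineage_screen(queries[:2], genomes, curate_family(queries[:2]))
    assert result.failures and "rat" in result.failures[0]
    assert all(p.incomplete and p.category is None for p in result.profiles.values())
    assert (result.lineage_table["category"] == "incomplete").all()
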