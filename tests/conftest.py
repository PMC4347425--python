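import numpy as np
import pytest

from orscout.seq import NucSeq

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def plant_homolog(
    rng: np.random.Generator, qlen: int, tlen: int, identity: float
) -> tuple[str, str]:
    """A random query and a random target containing a mutated copy of it."""
    q = random_dna(rng, qlen)
    t = list(random_dna(rng, tlen))
    seg = list(q)
    nmut = int(len(seg) * (1.0 - identity))
    for pos in rng.choice(len(seg), nmut, replace=False):
        seg[pos] = BASES[int(rng.integers(0, 4))]
    ins = int(rng.integers(0, max(1, tlen - qlen)))
    t[ins:ins] = seg
    return q, "".join(t)


def biopython_local_score(query: str, target: str, params) -> float:
    """Independent optimal-local-alignment oracle (Biopython DP)."""
    from Bio import Align

    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = params.match
    a.mismatch_score = params.mismatch
    a.open_gap_score = params.gap_open
    a.extend_gap_score = params.gap_extend
    return a.score(query, target)


@pytest.fixture(scope="session")
def lineage_cohort():
    """Ten-query cohort: 8 shared orthologs at ~85% identity, one human-only,
    one human+chimp-only, with planted-gene truth."""
    from orscout.synthetic import simulate_lineage_cohort

    categories = {f"g{i:02d}": "shared" for i in range(8)}
    categories["g08"] = "human_only"
    categories["g09"] = "human_chimp_only"
    return simulate_lineage_cohort(categories, seed=20260919)


@pytest.fixture(scope="session")
def demo_screen():
    """One simulated plate screen (9 receptors x 37 odorants) plus its truth."""
    from orscout.synthetic import demo_agonist_truth, simulate_plate_dataset

    or_names = [f"OR{i}" for i in range(1, 10)]
    odorants = [f"od{i:02d}" for i in range(1, 38)]
    truth_map = demo_agonist_truth(or_names, odorants)
    wells, truth = simulate_plate_dataset(or_names, odorants, truth_map, seed=11)
    return wells, truth, truth_map
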