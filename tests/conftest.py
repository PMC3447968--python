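import numpy as np
import pytest

from interolog import HomologyMap, Interactome, PairScore


@pytest.fixture
def toy_source():
    return Interactome.from_pairs("S", [("a1", "a2"), ("a1", "a3")])


@pytest.fixture
def toy_map():
    return HomologyMap(
        "curated", "S", "T",
        {
            ("a1", "b1"): PairScore(1e-30, 80.0),
            ("a2", "b2"): PairScore(1e-20, 60.0),
            ("a2", "b4"): PairScore(1e-12, 40.0),
            ("a3", "b3"): PairScore(1e-15, 50.0),
        },
    )


@pytest.fixture
def toy_target():
    return Interactome.from_pairs("T", [("b1", "b2"), ("b3", "b5")])


def random_interactome(rng: np.random.Generator, species: str, n_proteins: int,
                       n_edges: int, prefix: str = "p") -> Interactome:
    proteins = [f"{prefix}{i}" for i in range(n_proteins)]
    pairs = set()
    guard = 0
    while len(pairs) < n_edges and guard < 50 * n_edges:
        guard += 1
        i, j = rng.integers(0, n_proteins, size=2)
        if i != j:
            pairs.add(tuple(sorted((proteins[i], proteins[j]))))
    return Interactome.from_pairs(species, pairs)


def random_cross_map(rng: np.random.Generator, n_s: int, n_t: int,
                     n_pairs: int) -> HomologyMap:
    pairs = {}
    for _ in range(n_pairs):
        a = f"p{rng.integers(0, n_s)}"
        b = f"q{rng.integers(0, n_t)}"
        pairs[(a, b)] = PairScore(float(10.0 ** -rng.integers(5, 60)), None)
    return HomologyMap("reciprocal_hits", "S", "T", pairs)


def random_within_map(rng: np.random.Generator, n: int, n_pairs: int,
                      species: str = "S", prefix: str = "p") -> HomologyMap:
    pairs = {}
    for _ in range(n_pairs):
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        key = tuple(sorted((f"{prefix}{i}", f"{prefix}{j}")))
        pairs[key] = PairScore(float(10.0 ** -rng.integers(5, 60)), None)
    return HomologyMap("reciprocal_hits", species, species, pairs)
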