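import numpy as np
import pandas as pd
import pytest

from pasmatch.io import ExpressionMatrix, GeneSetCollection, class_labels
from pasmatch.pas import pas_matrix
from pasmatch.selection import select_pathways
from pasmatch.simulate import ExpressionSimSpec, simulate_expression


@pytest.fixture
def tiny_expression() -> ExpressionMatrix:
    """5 genes x 3 samples with strictly decreasing values in sample s1."""
    values = pd.DataFrame(
        {
            "s1": [10.0, 8.0, 6.0, 4.0, 2.0],
            "s2": [1.0, 2.0, 3.0, 4.0, 5.0],
            "s3": [5.0, 5.0, 1.0, 0.0, 2.0],
        },
        index=["g1", "g2", "g3", "g4", "g5"],
    )
    return ExpressionMatrix(values)


@pytest.fixture
def small_sets() -> GeneSetCollection:
    return GeneSetCollection(
        sets={
            "P24": frozenset({"g2", "g4"}),
            "Ptop": frozenset({"g1"}),
            "Pall": frozenset({"g1", "g2", "g3", "g4", "g5"}),
        }
    )


def random_instance(rng: np.random.Generator, n_genes: int, n_samples: int, n_sets: int):
    """A random small expression matrix + gene-set collection for oracle tests."""
    genes = [f"g{i:03d}" for i in range(n_genes)]
    values = pd.DataFrame(
        rng.gamma(2.0, 50.0, size=(n_genes, n_samples)),
        index=genes,
        columns=[f"s{j}" for j in range(n_samples)],
    )
    # inject ties so the tie-break rule is exercised
    if n_genes >= 4:
        values.iloc[1] = values.iloc[0]
    sets = {}
    for s in range(n_sets):
        size = int(rng.integers(1, max(2, n_genes // 2)))
        members = rng.choice(genes, size=size, replace=False).tolist()
        # occasionally include a gene absent from the matrix
        if rng.random() < 0.3:
            members.append(f"missing{s}")
        sets[f"S{s}"] = frozenset(members)
    return ExpressionMatrix(values), GeneSetCollection(sets=sets)


def brute_force_pas(matrix: ExpressionMatrix, sets: GeneSetCollection, k: int) -> pd.DataFrame:
    """Direct-summation PAS oracle, independent of the vectorized implementation."""
    out = pd.DataFrame(index=list(sets), columns=matrix.sample_ids, dtype=float)
    for sample in matrix.sample_ids:
        pairs = sorted(
            ((g, matrix.values.at[g, sample]) for g in matrix.gene_ids),
            key=lambda p: (-p[1], p[0]),
        )
        ranks = {g: i + 1 for i, (g, _) in enumerate(pairs)}
        for name, members in sets.items():
            total = 0.0
            for g in members:
                if g in ranks:
                    total += max(k - ranks[g], 0)
            out.at[name, sample] = total / (len(members) * k)
    return out


# ---- shared planted-truth simulation (the study-sized recovery setting) ----


@pytest.fixture(scope="session")
def planted_world():
    """3 classes x 20 samples, 200 pathways, 10 planted per class, effect 2."""
    spec = ExpressionSimSpec(seed=7)
    matrix, sets, annotation, planted = simulate_expression(spec)
    return spec, matrix, sets, annotation, planted


@pytest.fixture(scope="session")
def planted_pas(planted_world):
    _, matrix, sets, _, _ = planted_world
    return pas_matrix(matrix, sets, k=3000)


@pytest.fixture(scope="session")
def planted_labels(planted_world, planted_pas):
    _, _, _, annotation, _ = planted_world
    return class_labels(annotation, planted_pas.sample_ids)


@pytest.fixture(scope="session")
def planted_selection(planted_pas, planted_labels):
    return select_pathways(planted_pas, planted_labels, penalty="auto", seed=7)


@pytest.fixture(scope="session")
def small_planted_world():
    """Smaller 2-class planted world for permutation-null and speed-bound tests."""
    spec = ExpressionSimSpec(
        seed=11,
        n_genes=1500,
        n_pathways=80,
        n_samples_per_class=8,
        class_labels=("A", "B"),
        n_active_per_class=5,
    )
    matrix, sets, annotation, planted = simulate_expression(spec)
    pas = pas_matrix(matrix, sets, k=750)
    labels = class_labels(annotation, pas.sample_ids)
    return spec, pas, labels, planted
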