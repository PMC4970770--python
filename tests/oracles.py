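"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the package's own code paths: column
selection by a per-column scan, haplotype partitioning by union-find over
pairwise comparisons, and inertia by the direct chi-square loop.
"""

from __future__ import annotations

import numpy as np

UNAMBIGUOUS = set("ACGT")


def brute_force_select_columns(sequences: dict[str, str], policy: str) -> list[int]:
    """Scan every column; keep it unless any sequence has a non-ACGT char
    (exclude_columns), or keep all (literal)."""
    length = len(next(iter(sequences.values())))
    if policy == "literal":
        return list(range(length))
    keep = []
    for col in range(length):
        if all(seq[col] in UNAMBIGUOUS for seq in sequences.values()):
            keep.append(col)
    return keep


def brute_force_partition(
    sequences: dict[str, str], species_of: dict[str, str], columns: list[int]
) -> set[frozenset]:
    """Transitive closure of the pairwise relation 'same species and
    identical on the selected columns', via union-find."""
    ids = list(sequences)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if species_of[a] != species_of[b]:
                continue
            if all(sequences[a][c] == sequences[b][c] for c in columns):
                union(a, b)
    groups: dict[str, set] = {}
    for x in ids:
        groups.setdefault(find(x), set()).add(x)
    return {frozenset(g) for g in groups.values()}


def chi_square_over_n(X: np.ndarray) -> float:
    """Direct double loop: sum (x_ij - e_ij)^2 / e_ij over all cells,
    divided by the grand total."""
    X = np.asarray(X, dtype=float)
    n = X.sum()
    rows = X.sum(axis=1)
    cols = X.sum(axis=0)
    chi2 = 0.0
    for i in range(X.shape[0]):
        for j in range(X.shape[1]):
            e = rows[i] * cols[j] / n
            chi2 += (X[i, j] - e) ** 2 / e
    return chi2 / n


def residual_eigenvalues(X: np.ndarray) -> np.ndarray:
    """Eigenvalues (descending, positives only) of S S^T for the
    standardised residual matrix S — the axis inertias, by dense
    eigendecomposition rather than SVD."""
    X = np.asarray(X, dtype=float)
    n = X.sum()
    r = X.sum(axis=1) / n
    c = X.sum(axis=0) / n
    S = (X / n - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    vals = np.linalg.eigvalsh(S @ S.T)[::-1]
    return vals[vals > 1e-12]


def random_count_table(rng: np.random.Generator, max_dim: int = 10) -> np.ndarray:
    """A random count table with no zero margins."""
    while True:
        shape = (rng.integers(2, max_dim + 1), rng.integers(2, max_dim + 1))
        X = rng.integers(0, 21, size=shape)
        if (X.sum(axis=1) > 0).all() and (X.sum(axis=0) > 0).all():
            return X


def random_alignment(
    rng: np.random.Generator, max_seqs: int = 20, max_cols: int = 60
) -> tuple[dict[str, str], dict[str, str]]:
    """A random gapped alignment built from a few templates with sparse
    mutations (so haplotype collisions actually happen), plus species
    labels. Alphabet: A/C/G/T plus '-' and 'N' noise."""
    n = int(rng.integers(2, max_seqs + 1))
    length = int(rng.integers(4, max_cols + 1))
    n_templates = int(rng.integers(1, 6))
    templates = [
        "".join(rng.choice(list("ACGT"), size=length)) for _ in range(n_templates)
    ]
    species_pool = [f"T. sp{k}" for k in range(int(rng.integers(1, 4)))]
    sequences: dict[str, str] = {}
    species_of: dict[str, str] = {}
    for i in range(n):
        seq = list(templates[int(rng.integers(n_templates))])
        for pos in range(length):
            u = rng.random()
            if u < 0.03:
                seq[pos] = "-"
            elif u < 0.05:
                seq[pos] = "N"
            elif u < 0.10:
                seq[pos] = "ACGT"[int(rng.integers(4))]
        sid = f"iso{i:02d}"
        sequences[sid] = "".join(seq)
        species_of[sid] = species_pool[int(rng.integers(len(species_pool)))]
    return sequences, species_of
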