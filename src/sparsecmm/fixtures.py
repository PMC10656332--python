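"""Small reference tables used throughout the documentation and tests.

Each builder returns a fresh :class:`~sparsecmm.contingency.SparseTable`.
The catalog maps a stable name to (builder, description); the CLI
``fixtures`` command writes each one as a frequency TSV plus a manifest.
"""

from __future__ import annotations

import json
import os

from .contingency import SparseTable, build_table, index_to_pattern, write_frequency_tsv

__all__ = [
    "three_item_example",
    "single_cell_2x2",
    "diagonal_2x2",
    "guttman_pair",
    "two_pattern_sparse",
    "FIXTURES",
    "write_fixtures",
]


def _from_dense(counts, cats):
    pairs = [
        (index_to_pattern(i, cats), c) for i, c in enumerate(counts) if c > 0
    ]
    return build_table(pairs, cats=cats)


def three_item_example() -> SparseTable:
    """130 respondents on three binary items a, b, c.

    The running example for the marginal-homogeneity, alpha and
    scalability models: pattern 100 is unobserved, the rest carry
    counts (20, 15, 10, 15, 15, 25, 30)."""
    return _from_dense([20, 15, 10, 15, 0, 15, 25, 30], (2, 2, 2))


def single_cell_2x2() -> SparseTable:
    """One observation in the single off-diagonal cell 01 of a 2×2 table;
    the marginal-homogeneity constraint is infeasible on the observed
    support (the empty-set / first-order problem)."""
    return _from_dense([0, 1, 0, 0], (2, 2))


def diagonal_2x2() -> SparseTable:
    """Two observations on the diagonal of a 2×2 table; marginal
    homogeneity holds trivially but its statistic has zero variance on the
    observed support (the second-order problem)."""
    return _from_dense([1, 0, 0, 1], (2, 2))


def guttman_pair() -> SparseTable:
    """Two binary items, counts (30, 0, 30, 30): the Guttman-error cell 01
    is empty, so both scalability coefficients degenerate to 1 on the
    observed support and no restricted fit can reach H = 0.3."""
    return _from_dense([30, 0, 30, 30], (2, 2))


def two_pattern_sparse() -> SparseTable:
    """Three binary items, 130 respondents concentrated on the two patterns
    100 and 110 (65 each): the extreme-sparsity example for support
    augmentation under the marginal-homogeneity model."""
    return _from_dense([0, 0, 0, 0, 65, 0, 65, 0], (2, 2, 2))


FIXTURES = {
    "three_items_130": (
        three_item_example,
        "130 respondents on three binary items; running example for the "
        "mean, alpha and scalability models",
    ),
    "single_cell_2x2": (
        single_cell_2x2,
        "single observed off-diagonal cell; first-order (empty-set) problem "
        "under marginal homogeneity",
    ),
    "diagonal_2x2": (
        diagonal_2x2,
        "diagonal-only 2x2 table; second-order (zero-variance) problem "
        "under marginal homogeneity",
    ),
    "guttman_pair": (
        guttman_pair,
        "item pair with an empty Guttman-error cell; scalability "
        "coefficients degenerate to 1",
    ),
    "two_pattern_sparse": (
        two_pattern_sparse,
        "two observed patterns out of eight; support-augmentation example",
    ),
}


def write_fixtures(out_dir) -> list:
    """Write every fixture as `<name>.tsv` plus `manifest.json`; returns paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    manifest = {}
    for name, (builder, description) in FIXTURES.items():
        table = builder()
        path = os.path.join(out_dir, f"{name}.tsv")
        write_frequency_tsv(table, path)
        paths.append(path)
        manifest[name] = {
            "file": f"{name}.tsv",
            "description": description,
            "J": table.J,
            "cats": list(table.cats),
            "N": int(table.N),
            "support_size": table.support_size,
        }
    mpath = os.path.join(out_dir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2)
    paths.append(mpath)
    return paths
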