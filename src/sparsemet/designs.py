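"""Sparse phenotyping designs: line allocation, environment assignment, masking.

A sparse design splits the lines into one full set (FS, phenotyped in every
environment) and one or more sparse sets (SS, phenotyped only in a subset of
environments — possibly none, in which case the sparse lines are predicted
purely through the genomic relationship).  Fourteen built-in designs
(SP1..SP14) cover two full-set sizes (104 or 154 of 304 lines), one to ten
sparse sets, zero to four tested environments per sparse set, and balanced
vs unbalanced assignment of untested environments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

__all__ = [
    "SparseDesignSpec",
    "Allocation",
    "MaskIndex",
    "builtin_designs",
    "get_design",
    "scale_design",
    "plots_saved_fraction",
    "assign_environments",
    "allocate_lines",
    "mask_phenotypes",
]


@dataclass(frozen=True)
class SparseDesignSpec:
    """Parameterization of one sparse phenotyping design."""

    design_id: str
    n_full: int
    n_sparse_sets: int
    n_tested_env_per_ss: int
    balanced: bool
    n_env: int = 5
    n_lines: int = 304

    def __post_init__(self):
        if not (1 <= self.n_full < self.n_lines):
            raise ValueError("n_full must be in [1, n_lines)")
        if self.n_sparse_sets < 1:
            raise ValueError("need at least one sparse set")
        if not (0 <= self.n_tested_env_per_ss < self.n_env):
            raise ValueError("tested environments per SS must be in [0, n_env)")
        if self.balanced and self.n_sparse_sets > comb(self.n_env, self.n_untested_env):
            raise ValueError(
                f"{self.design_id}: balanced design needs n_sparse_sets <= "
                f"C({self.n_env},{self.n_untested_env})")

    @property
    def n_sparse_lines(self) -> int:
        return self.n_lines - self.n_full

    @property
    def n_untested_env(self) -> int:
        return self.n_env - self.n_tested_env_per_ss

    @property
    def lines_per_ss(self) -> int:
        if self.n_sparse_lines % self.n_sparse_sets:
            raise ValueError(
                f"{self.design_id}: {self.n_sparse_lines} sparse lines not "
                f"divisible into {self.n_sparse_sets} equal sets")
        return self.n_sparse_lines // self.n_sparse_sets


# (n_sparse_sets, n_tested_env_per_ss, balanced) per design family row.
_FAMILY_ROWS = [
    (5, 4, True),
    (10, 3, True),
    (10, 2, True),
    (5, 1, True),
    (1, 0, True),
    (5, 3, False),
    (5, 2, False),
]


def builtin_designs() -> list[SparseDesignSpec]:
    """The 14 designs: SP1-SP7 with 104 full-set lines, SP8-SP14 with 154."""
    specs = []
    for fam, n_full in ((0, 104), (7, 154)):
        for i, (n_ss, n_tested, balanced) in enumerate(_FAMILY_ROWS):
            specs.append(SparseDesignSpec(
                design_id=f"SP{fam + i + 1}", n_full=n_full,
                n_sparse_sets=n_ss, n_tested_env_per_ss=n_tested,
                balanced=balanced))
    return specs


def get_design(design_id: str) -> SparseDesignSpec:
    for spec in builtin_designs():
        if spec.design_id == design_id:
            return spec
    raise KeyError(f"unknown design {design_id!r}")


def scale_design(spec: SparseDesignSpec, n_lines: int, n_full: int,
                 suffix: str = "s") -> SparseDesignSpec:
    """Analogue of a design at a different population size.

    Keeps the set/environment structure, rescales the full set.  The caller
    chooses n_full so that the sparse lines divide evenly over the sets.
    """
    scaled = SparseDesignSpec(
        design_id=f"{spec.design_id}{suffix}", n_full=n_full,
        n_sparse_sets=spec.n_sparse_sets,
        n_tested_env_per_ss=spec.n_tested_env_per_ss,
        balanced=spec.balanced, n_env=spec.n_env, n_lines=n_lines)
    scaled.lines_per_ss  # validate divisibility eagerly
    return scaled


def plots_saved_fraction(spec: SparseDesignSpec) -> float:
    """Percentage of line x environment plots not phenotyped under the design."""
    return 100.0 * spec.n_sparse_lines * spec.n_untested_env / (
        spec.n_lines * spec.n_env)


def assign_environments(spec: SparseDesignSpec, seed) -> list[frozenset]:
    """Tested-environment sets (as frozensets of env indices) per sparse set.

    Balanced designs use pairwise-distinct untested combinations with
    coverage as even as possible: when the number of sparse sets equals the
    number of untested-environment combinations every combination is used
    exactly once, and when it equals the number of environments a rotated
    window leaves each environment untested equally often.  Unbalanced
    designs draw distinct combinations at random with no coverage guarantee.
    """
    rng = np.random.default_rng(seed)
    n_env, n_un = spec.n_env, spec.n_untested_env
    envs = list(range(n_env))
    combos = list(itertools.combinations(envs, n_un))
    if spec.balanced:
        if spec.n_sparse_sets > len(combos):
            raise ValueError("balanced design exceeds available combinations")
        if spec.n_sparse_sets == len(combos):
            idx = rng.permutation(len(combos))
            untested = [set(combos[i]) for i in idx]
        elif spec.n_sparse_sets == n_env:
            perm = rng.permutation(n_env)
            untested = [{int(perm[(i + j) % n_env]) for j in range(n_un)}
                        for i in range(n_env)]
        else:
            # greedy even-coverage pick among distinct combinations
            coverage = np.zeros(n_env)
            remaining = combos.copy()
            untested = []
            for _ in range(spec.n_sparse_sets):
                loads = np.array([coverage[list(c)].sum() for c in remaining])
                best = np.flatnonzero(loads == loads.min())
                pick = remaining.pop(int(rng.choice(best)))
                coverage[list(pick)] += 1
                untested.append(set(pick))
    else:
        idx = rng.choice(len(combos), size=spec.n_sparse_sets, replace=False)
        untested = [set(combos[i]) for i in idx]
    return [frozenset(set(envs) - u) for u in untested]


@dataclass
class Allocation:
    """One realized random split of lines into FS and sparse sets."""

    spec: SparseDesignSpec
    full_set: list
    sparse_sets: list
    ss_env_map: list  # frozenset of tested env indices per sparse set
    seed: object = None

    def __post_init__(self):
        sets = [self.full_set] + list(self.sparse_sets)
        flat = [l for s in sets for l in s]
        if len(flat) != len(set(flat)):
            raise ValueError("allocation sets are not disjoint")
        if len(flat) != self.spec.n_lines:
            raise ValueError("allocation does not cover all lines")
        sizes = {len(s) for s in self.sparse_sets}
        if len(sizes) > 1:
            raise ValueError("sparse sets must be equally sized")
        for tested in self.ss_env_map:
            if len(tested) != self.spec.n_tested_env_per_ss:
                raise ValueError("tested-environment set has wrong size")

    @property
    def sparse_lines(self) -> list:
        return [l for s in self.sparse_sets for l in s]

    def to_frame(self) -> pd.DataFrame:
        rows = [(l, "FS") for l in self.full_set]
        for i, s in enumerate(self.sparse_sets):
            rows += [(l, f"SS{i + 1}") for l in s]
        return pd.DataFrame(rows, columns=["line", "set_label"])


def allocate_lines(spec: SparseDesignSpec, line_ids, seed) -> Allocation:
    """Uniform random split of line_ids into FS and equal sparse sets."""
    line_ids = list(line_ids)
    if len(line_ids) != spec.n_lines:
        raise ValueError(
            f"{len(line_ids)} line ids for a design with n_lines={spec.n_lines}")
    per_ss = spec.lines_per_ss  # raises on non-divisible sparse count
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(line_ids))
    shuffled = [line_ids[i] for i in perm]
    full = sorted(shuffled[:spec.n_full])
    sparse = shuffled[spec.n_full:]
    sets = [sorted(sparse[i * per_ss:(i + 1) * per_ss])
            for i in range(spec.n_sparse_sets)]
    env_map = assign_environments(spec, rng)
    return Allocation(spec, full, sets, env_map, seed=seed)


@dataclass
class MaskIndex:
    """Cells (line, environment label) removed by a sparse design."""

    cells: set
    fraction: float  # percent of line x env cells masked

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.cells), columns=["line", "env"])


def mask_phenotypes(adjusted: pd.DataFrame, alloc: Allocation,
                    environments: list | None = None
                    ) -> tuple[pd.DataFrame, MaskIndex]:
    """Drop all tester records of each sparse line in its untested environments.

    ``adjusted`` is a tidy line/tester/env/value table covering the full
    grid.  Environment indices in the allocation map onto the sorted unique
    environment labels unless an explicit order is given.
    """
    if environments is None:
        environments = sorted(adjusted["env"].unique())
    if len(environments) != alloc.spec.n_env:
        raise ValueError("environment count does not match the design")
    table_lines = set(adjusted["line"].unique())
    alloc_lines = set(alloc.full_set) | set(alloc.sparse_lines)
    if table_lines != alloc_lines:
        raise ValueError("allocation lines do not match the phenotype table")
    cells = set()
    all_env = set(range(alloc.spec.n_env))
    for lines, tested in zip(alloc.sparse_sets, alloc.ss_env_map):
        for e in all_env - set(tested):
            cells.update((l, environments[e]) for l in lines)
    frac = 100.0 * len(cells) / (alloc.spec.n_lines * alloc.spec.n_env)
    key = pd.MultiIndex.from_frame(adjusted[["line", "env"]])
    masked = adjusted[~key.isin(cells)].reset_index(drop=True)
    return masked, MaskIndex(cells, frac)
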