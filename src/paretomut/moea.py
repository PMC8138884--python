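"""NSGA-II-based multi-objective search for Pareto-optimal gene selections.

The optimization problem: given a binary alteration matrix over a gene
universe, find the set of non-dominated gene subsets that trade off

* maximal sample coverage gamma(G), against
* minimal overlap omega(G) (``coverage_overlap`` mode) or minimal subset
  size |G| (``coverage_size`` mode).

The search is a generational NSGA-II: a population of ``mu`` binary gene
membership vectors is evolved for ``k`` iterations; each iteration produces
``mu`` offspring via tournament selection, uniform crossover and per-gene
bit-flip mutation, evaluates them (exactly ``mu`` objective evaluations per
iteration, ``mu * k`` over the run), and truncates parents + offspring back
to ``mu`` by non-domination rank and crowding distance.  All evaluated
solutions feed an external elitist archive; the returned Pareto set is the
non-dominated subset of everything ever evaluated, deduplicated to one
representative selection per objective vector (the lexicographically
smallest gene set) and sorted by coverage.

``pareto_front_exact`` provides a brute-force enumeration oracle for small
instances, sharing the same dedup/sort contract.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .metrics import (
    COVERAGE_OVERLAP,
    AlterationMatrix,
    GeneSelection,
    ObjectiveVector,
    _check_mode,
)

# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimpleSetup:
    """User-facing optimization setup in directly interpretable units.

    Defaults are the reference HNSCC use-case configuration
    (population 100, 5 expected solution combinations, 20 initially
    selected genes, 2 swapped genes in expectation, selection pressure 10,
    10^6 search steps).
    """

    population_size: int = 100
    solution_combination_count: int = 5
    initially_selected_genes: int = 20
    swapped_genes: int = 2
    selection_pressure: int = 10
    search_steps: int = 1_000_000

    def __post_init__(self):
        if self.population_size < 2 or self.population_size % 2:
            raise ConfigurationError("population_size must be even and >= 2")
        if self.search_steps < 1:
            raise ConfigurationError("search_steps must be >= 1")
        for name in ("solution_combination_count", "initially_selected_genes",
                     "swapped_genes", "selection_pressure"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.selection_pressure < 1:
            raise ConfigurationError("selection_pressure must be >= 1")


@dataclass(frozen=True)
class AlgorithmParams:
    """Low-level algorithm parameters (mu, p_cx, p_sel, p_mut, tau, k)."""

    mu: int
    p_cx: float
    p_sel: float
    p_mut: float
    tau: int
    k: int
    seed: int = 0

    def __post_init__(self):
        if self.mu < 2 or self.mu % 2:
            raise ConfigurationError("mu must be even and >= 2")
        for name in ("p_cx", "p_sel", "p_mut"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")
        if not 1 <= self.tau <= self.mu:
            raise ConfigurationError("tau must satisfy 1 <= tau <= mu")
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")


def simple_to_algorithm_params(
    setup: SimpleSetup, n_genes: int, seed: int = 0
) -> AlgorithmParams:
    """Map the simple setup onto algorithm parameters for an n-gene pool.

    mu = population size, k = search steps, tau = selection pressure,
    p_sel = initially_selected_genes / n_genes,
    p_mut = swapped_genes / n_genes,
    p_cx  = solution_combination_count / (mu / 2)   (crossover is decided
    per offspring pair, so mu/2 pairs at p_cx yield the configured number
    of expected combinations).
    """
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    mu = setup.population_size
    p_sel = setup.initially_selected_genes / n_genes
    p_mut = setup.swapped_genes / n_genes
    p_cx = setup.solution_combination_count / (mu / 2)
    for name, p in (("p_sel", p_sel), ("p_mut", p_mut), ("p_cx", p_cx)):
        if p > 1.0:
            raise ConfigurationError(
                f"simple setup implies {name} = {p:.4f} > 1 for an "
                f"{n_genes}-gene pool"
            )
    return AlgorithmParams(
        mu=mu, p_cx=p_cx, p_sel=p_sel, p_mut=p_mut,
        tau=setup.selection_pressure, k=setup.search_steps, seed=seed,
    )


def scheduled_evaluations(params: AlgorithmParams) -> int:
    """Objective evaluations scheduled for the generational loop (mu * k).

    The mu evaluations of the initial population are reported separately
    by :func:`evolve`.
    """
    return params.mu * params.k


# ---------------------------------------------------------------------------
# Pareto set container
# ---------------------------------------------------------------------------


def dominates(a: ObjectiveVector, b: ObjectiveVector) -> bool:
    """True iff a dominates b (>= coverage, <= second, strict somewhere)."""
    if a.mode != b.mode:
        raise ConfigurationError("cannot compare objective vectors of mixed modes")
    return (
        a.coverage >= b.coverage
        and a.second <= b.second
        and (a.coverage > b.coverage or a.second < b.second)
    )


@dataclass
class ParetoSet:
    """Mutually non-dominated (selection, objective vector) pairs.

    Entries carry pairwise distinct objective vectors (one representative
    selection each) and are sorted by coverage ascending.  ``n_evaluations``
    and ``n_initial_evaluations`` record the evaluation budget actually
    spent when the set was produced by :func:`evolve`.
    """

    entries: list[tuple[GeneSelection, ObjectiveVector]]
    mode: str
    n_evaluations: int | None = field(default=None, compare=False)
    n_initial_evaluations: int | None = field(default=None, compare=False)

    @classmethod
    def from_candidates(
        cls,
        pairs,
        mode: str,
        n_evaluations: int | None = None,
        n_initial_evaluations: int | None = None,
    ) -> "ParetoSet":
        """Reduce arbitrary (selection, vector) pairs to a valid Pareto set."""
        _check_mode(mode)
        best: dict[tuple[int, int], GeneSelection] = {}
        for sel, vec in pairs:
            if vec.mode != mode:
                raise ConfigurationError("objective vector mode mismatch")
            key = vec.as_tuple()
            cur = best.get(key)
            if cur is None or sel.members < cur.members:
                best[key] = sel
        keys = list(best)
        nd = [
            k for k in keys
            if not any(
                (o[0] >= k[0] and o[1] <= k[1] and o != k) for o in keys
            )
        ]
        nd.sort()
        entries = [(best[k], ObjectiveVector(k[0], k[1], mode)) for k in nd]
        return cls(entries, mode, n_evaluations, n_initial_evaluations)

    def vectors(self) -> list[tuple[int, int]]:
        return [vec.as_tuple() for _, vec in self.entries]

    def selections(self) -> list[GeneSelection]:
        return [sel for sel, _ in self.entries]

    def max_coverage_within_size(self, max_size: int):
        """Entry of maximal coverage among those with |G| <= max_size.

        Returns ``None`` when no entry satisfies the size constraint
        (note the empty selection, if present, always does for max_size
        >= 0).  Implements the "largest coverage and at most s
        genes" solution selector.
        """
        feasible = [e for e in self.entries if len(e[0]) <= max_size]
        if not feasible:
            return None
        return max(feasible, key=lambda e: (e[1].coverage, -len(e[0])))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


# ---------------------------------------------------------------------------
# NSGA-II building blocks (public, per-solution API)
# ---------------------------------------------------------------------------


def initialize_population(
    params: AlgorithmParams, genes, rng: np.random.Generator
) -> list[GeneSelection]:
    """mu random selections; each gene included i.i.d. with prob p_sel."""
    genes = list(genes)
    if not genes:
        raise ConfigurationError("candidate gene pool is empty")
    mask = rng.random((params.mu, len(genes))) < params.p_sel
    return [_selection_from_mask(row, genes) for row in mask]


def _selection_from_mask(mask: np.ndarray, genes: list[str]) -> GeneSelection:
    return GeneSelection(g for g, m in zip(genes, mask) if m)


def mutate(
    selection: GeneSelection, genes, p_mut: float, rng: np.random.Generator
) -> GeneSelection:
    """Flip each gene's membership bit independently with probability p_mut."""
    genes = list(genes)
    flips = rng.random(len(genes)) < p_mut
    members = set(selection.members)
    for g, f in zip(genes, flips):
        if f:
            members.symmetric_difference_update((g,))
    return GeneSelection(members)


def crossover(
    parent_a: GeneSelection,
    parent_b: GeneSelection,
    genes,
    p_cx: float,
    rng: np.random.Generator,
) -> tuple[GeneSelection, GeneSelection]:
    """Uniform crossover with pair-level probability p_cx.

    With probability ``p_cx`` each gene position swaps between the two
    children with probability 0.5; otherwise the children are copies of
    the parents.  Membership bits are conserved position-wise.
    """
    genes = list(genes)
    pool = set(genes)
    if not (set(parent_a.members) <= pool and set(parent_b.members) <= pool):
        raise ConfigurationError("parents are not bound to the given gene pool")
    if rng.random() >= p_cx:
        return parent_a, parent_b
    swap = rng.random(len(genes)) < 0.5
    a = set(parent_a.members)
    b = set(parent_b.members)
    for g, s in zip(genes, swap):
        if s and (g in a) != (g in b):
            if g in a:
                a.discard(g)
                b.add(g)
            else:
                b.discard(g)
                a.add(g)
    return GeneSelection(a), GeneSelection(b)


def nondominated_sort(vectors) -> list[list[int]]:
    """Partition objective vectors into fronts; returns index lists.

    Front 1 is the non-dominated set; front i is non-dominated once fronts
    1..i-1 are removed.  All vectors must share one objective mode.
    """
    vectors = list(vectors)
    if not vectors:
        return []
    modes = {v.mode for v in vectors}
    if len(modes) > 1:
        raise ConfigurationError("vectors of mixed objective modes")
    cov = np.array([v.coverage for v in vectors])
    sec = np.array([v.second for v in vectors])
    return [f.tolist() for f in _fronts(cov, sec)]


def crowding_distance(front) -> np.ndarray:
    """NSGA-II crowding distances for the vectors of one front.

    Boundary solutions per objective get infinite distance; interior
    distances sum the normalized neighbor gaps over both objectives.
    """
    front = list(front)
    if not front:
        raise ConfigurationError("front must be nonempty")
    cov = np.array([v.coverage for v in front], dtype=float)
    sec = np.array([v.second for v in front], dtype=float)
    return _crowding(cov, sec)


def tournament_select(
    population,
    ranks,
    crowding,
    tau: int,
    rng: np.random.Generator,
) -> GeneSelection:
    """Draw tau solutions with replacement; return the best one.

    "Best" means lower non-domination rank, then larger crowding distance,
    then a uniform random tie-break.
    """
    population = list(population)
    if not population:
        raise ConfigurationError("population is empty")
    ranks = np.asarray(ranks)
    crowding = np.asarray(crowding, dtype=float)
    draws = rng.integers(0, len(population), size=tau)
    best = draws[0]
    for i in draws[1:]:
        if ranks[i] < ranks[best] or (
            ranks[i] == ranks[best] and crowding[i] > crowding[best]
        ):
            best = i
        elif (
            ranks[i] == ranks[best]
            and crowding[i] == crowding[best]
            and rng.random() < 0.5
        ):
            best = i
    return population[best]


# ---------------------------------------------------------------------------
# Vectorized internals
# ---------------------------------------------------------------------------


def _evaluate(M: np.ndarray, pop: np.ndarray, mode: str):
    """Objective arrays for a population of membership rows.

    M : (n_samples, n_genes) int8;  pop : (m, n_genes) bool.
    Returns (coverage, second) int arrays of length m.
    """
    counts = pop.astype(np.int32) @ M.T.astype(np.int32)  # (m, n_samples)
    cov = (counts > 0).sum(axis=1)
    if mode == COVERAGE_OVERLAP:
        second = counts.sum(axis=1) - cov
    else:
        second = pop.sum(axis=1)
    return cov.astype(np.int64), second.astype(np.int64)


def _domination_matrix(cov: np.ndarray, sec: np.ndarray) -> np.ndarray:
    """dom[i, j] == True iff solution i dominates solution j."""
    ge_cov = cov[:, None] >= cov[None, :]
    le_sec = sec[:, None] <= sec[None, :]
    strict = (cov[:, None] > cov[None, :]) | (sec[:, None] < sec[None, :])
    return ge_cov & le_sec & strict


def _fronts(cov: np.ndarray, sec: np.ndarray) -> list[np.ndarray]:
    dom = _domination_matrix(cov, sec)
    n = len(cov)
    remaining = np.ones(n, dtype=bool)
    fronts: list[np.ndarray] = []
    while remaining.any():
        dominated = dom[remaining].any(axis=0) & remaining
        current = remaining & ~dominated
        if not current.any():  # cannot happen for a strict partial order
            current = remaining
        fronts.append(np.flatnonzero(current))
        remaining &= ~current
    return fronts


def _crowding(cov: np.ndarray, sec: np.ndarray) -> np.ndarray:
    n = len(cov)
    dist = np.zeros(n)
    for obj in (cov, sec):
        order = np.argsort(obj, kind="stable")
        dist[order[0]] = np.inf
        dist[order[-1]] = np.inf
        rng_ = obj[order[-1]] - obj[order[0]]
        if n > 2 and rng_ > 0:
            gaps = (obj[order[2:]] - obj[order[:-2]]) / rng_
            dist[order[1:-1]] += gaps
    return dist


def _rank_and_crowding(cov: np.ndarray, sec: np.ndarray):
    fronts = _fronts(cov, sec)
    ranks = np.empty(len(cov), dtype=np.int64)
    crowd = np.empty(len(cov), dtype=float)
    for r, f in enumerate(fronts, start=1):
        ranks[f] = r
        crowd[f] = _crowding(cov[f].astype(float), sec[f].astype(float))
    return ranks, crowd


def _environmental_select(cov, sec, mu: int) -> np.ndarray:
    """Indices of the mu survivors by rank then crowding (NSGA-II truncation)."""
    fronts = _fronts(cov, sec)
    chosen: list[int] = []
    for f in fronts:
        if len(chosen) + len(f) <= mu:
            chosen.extend(f.tolist())
        else:
            need = mu - len(chosen)
            cd = _crowding(cov[f].astype(float), sec[f].astype(float))
            order = np.lexsort((f, -cd))  # crowding desc, index asc for ties
            chosen.extend(f[order[:need]].tolist())
            break
    return np.asarray(chosen, dtype=np.intp)


class _Archive:
    """Elitist archive: non-dominated objective vectors of all evaluations.

    Keeps one representative per vector, preferring the lexicographically
    smallest gene set.
    """

    def __init__(self, genes: list[str]):
        self.genes = np.asarray(genes, dtype=object)
        # sort positions so that membership rows iterate in name order
        self._name_order = np.argsort(self.genes, kind="stable")
        self.best: dict[tuple[int, int], tuple[str, ...]] = {}

    def _members(self, row: np.ndarray) -> tuple[str, ...]:
        picked = self._name_order[row[self._name_order]]
        return tuple(self.genes[picked])

    def update(self, pop: np.ndarray, cov: np.ndarray, sec: np.ndarray) -> None:
        keys = list(self.best)
        if keys:
            kc = np.array([k[0] for k in keys])
            ks = np.array([k[1] for k in keys])
        for i in range(len(pop)):
            key = (int(cov[i]), int(sec[i]))
            if keys:
                strictly_dom = (
                    (kc >= key[0]) & (ks <= key[1])
                    & ((kc > key[0]) | (ks < key[1]))
                )
                if strictly_dom.any():
                    continue
            members = self._members(pop[i])
            cur = self.best.get(key)
            if cur is None or members < cur:
                self.best[key] = members
        # prune newly dominated keys
        keys = list(self.best)
        kc = np.array([k[0] for k in keys])
        ks = np.array([k[1] for k in keys])
        dom = _domination_matrix(kc, ks)
        keep = ~dom.any(axis=0)
        self.best = {k: self.best[k] for k, kp in zip(keys, keep) if kp}

    def to_pareto_set(self, mode: str, n_eval: int, n_init: int) -> ParetoSet:
        entries = [
            (GeneSelection(members), ObjectiveVector(key[0], key[1], mode))
            for key, members in sorted(self.best.items())
        ]
        return ParetoSet(entries, mode, n_evaluations=n_eval,
                         n_initial_evaluations=n_init)


# ---------------------------------------------------------------------------
# Main loop and exact oracle
# ---------------------------------------------------------------------------


def evolve(
    matrix: AlterationMatrix,
    candidate_genes,
    mode: str,
    params: AlgorithmParams,
    progress_callback=None,
) -> ParetoSet:
    """Run the NSGA-II search and return the archived Pareto set.

    ``progress_callback(iteration, n_evaluations)`` is invoked after every
    iteration.  Deterministic for a fixed (matrix, params, seed).
    """
    _check_mode(mode)
    genes = list(candidate_genes)
    if not genes:
        raise ConfigurationError("candidate_genes must be nonempty")
    if len(set(genes)) != len(genes):
        raise ConfigurationError("candidate_genes contains duplicates")
    idx = matrix.column_indices(genes)
    M = matrix.values[:, idx]
    n = len(genes)
    mu, tau = params.mu, params.tau
    rng = np.random.default_rng(params.seed)

    pop = rng.random((mu, n)) < params.p_sel
    cov, sec = _evaluate(M, pop, mode)
    archive = _Archive(genes)
    archive.update(pop, cov, sec)
    n_init = mu
    n_eval = 0

    half = mu // 2
    for iteration in range(1, params.k + 1):
        ranks, crowd = _rank_and_crowding(cov, sec)
        # total preference order: rank asc, crowding desc, random tie-break
        tiebreak = rng.permutation(mu)
        order = np.lexsort((tiebreak, -crowd, ranks))
        quality = np.empty(mu, dtype=np.int64)
        quality[order] = np.arange(mu)
        draws = rng.integers(0, mu, size=(mu, tau))
        winners = draws[np.arange(mu), np.argmin(quality[draws], axis=1)]
        off = pop[winners].copy()

        do_cx = rng.random(half) < params.p_cx
        swap = (rng.random((half, n)) < 0.5) & do_cx[:, None]
        a, b = off[0::2].copy(), off[1::2].copy()
        off[0::2] = np.where(swap, b, a)
        off[1::2] = np.where(swap, a, b)

        off ^= rng.random((mu, n)) < params.p_mut

        ocov, osec = _evaluate(M, off, mode)
        n_eval += mu
        archive.update(off, ocov, osec)

        all_pop = np.concatenate([pop, off])
        all_cov = np.concatenate([cov, ocov])
        all_sec = np.concatenate([sec, osec])
        survivors = _environmental_select(all_cov, all_sec, mu)
        pop, cov, sec = all_pop[survivors], all_cov[survivors], all_sec[survivors]

        if progress_callback is not None:
            progress_callback(iteration, n_eval)

    return archive.to_pareto_set(mode, n_eval, n_init)


def pareto_front_exact(
    matrix: AlterationMatrix,
    candidate_genes=None,
    mode: str = COVERAGE_OVERLAP,
    max_genes: int = 20,
) -> ParetoSet:
    """Exact Pareto set by enumerating all 2^n gene subsets.

    Refuses pools larger than ``max_genes`` explicitly (never truncates).
    Shares the dedup/sort contract of :func:`evolve`: one representative
    selection (lexicographically smallest gene set) per objective vector,
    sorted by coverage ascending.
    """
    _check_mode(mode)
    genes = list(candidate_genes) if candidate_genes is not None else matrix.gene_ids
    n = len(genes)
    if n > max_genes:
        raise ConfigurationError(
            f"exact enumeration refused: {n} genes > max_genes={max_genes}"
        )
    if n == 0:
        empty = GeneSelection()
        return ParetoSet([(empty, ObjectiveVector(0, 0, mode))], mode)
    idx = matrix.column_indices(genes)
    M = matrix.values[:, idx]
    codes = np.arange(2 ** n, dtype=np.int64)
    bits = ((codes[:, None] >> np.arange(n)) & 1).astype(bool)
    cov, sec = _evaluate(M, bits, mode)

    # non-dominated unique vectors
    vecs = np.stack([cov, sec], axis=1)
    uniq = np.unique(vecs, axis=0)
    dom = _domination_matrix(uniq[:, 0], uniq[:, 1])
    nd = uniq[~dom.any(axis=0)]

    name_order = np.argsort(np.asarray(genes, dtype=object), kind="stable")
    genes_arr = np.asarray(genes, dtype=object)
    entries = []
    for c, s in nd:
        matches = np.flatnonzero((cov == c) & (sec == s))
        reps = []
        for m in matches:
            row = bits[m]
            reps.append(tuple(genes_arr[name_order[row[name_order]]]))
        members = min(reps)
        entries.append(
            (GeneSelection(members), ObjectiveVector(int(c), int(s), mode))
        )
    entries.sort(key=lambda e: e[1].as_tuple())
    return ParetoSet(entries, mode)


def brute_force_entries(matrix, genes, mode):
    """All (selection, vector) pairs over every subset (test helper oracle)."""
    out = []
    for r in range(len(genes) + 1):
        for combo in itertools.combinations(genes, r):
            sel = GeneSelection(combo)
            from .metrics import objective_vector

            out.append((sel, objective_vector(sel, matrix, mode)))
    return out
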