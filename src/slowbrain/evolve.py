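"""Multi-objective evolutionary fitting of the whole-brain model (NSGA-II).

The six free parameters (external drives mu_E_ext and mu_I_ext, adaptation
strength b and timescale tau_A, global coupling K_gl, noise strength
sigma_ou) are searched with the NSGA-II algorithm: non-dominated sorting,
crowding-distance-based tournament selection, simulated binary crossover and
polynomial mutation, with elitist merge-then-truncate survival.  Candidate
evaluations are stage-wise: a short screening simulation discards silent or
implausible dynamics before the expensive full-length run that computes the
FC / FCD / EEG-spectrum fitness vector.

The generic optimizer (:func:`nsga2_evolve`) is independent of the brain
model and is validated against an analytic Pareto front in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bold import bold_transform
from .network import Connectome, simulate_network
from .objectives import (
    FitnessVector,
    compute_fc,
    compute_fcd,
    fc_similarity,
    fcd_distance,
    spectrum_fit,
)
from .params import FREE_PARAM_BOUNDS, NodeParams

__all__ = [
    "GENE_NAMES",
    "GENE_BOUNDS",
    "Individual",
    "FitTargets",
    "fast_non_dominated_sort",
    "crowding_distance",
    "sbx_crossover",
    "polynomial_mutation",
    "nsga2_evolve",
    "stagewise_evaluate",
    "evolve_brain_model",
    "score_individuals",
]

GENE_NAMES = ("mu_E_ext", "mu_I_ext", "b", "tau_A", "K_gl", "sigma_ou")
GENE_BOUNDS = np.array([FREE_PARAM_BOUNDS[g] for g in GENE_NAMES])

# canonical NSGA-II operator constants
ETA_CROSSOVER = 20.0
ETA_MUTATION = 20.0
P_CROSSOVER = 0.9
P_MUTATION = 1.0 / len(GENE_NAMES)
TOURNAMENT_SIZE = 2


@dataclass
class Individual:
    genome: np.ndarray
    objectives: tuple | None = None   # minimization tuple, None if invalid
    fitness: FitnessVector | None = None
    generation: int = 0
    rank: int = -1
    crowding: float = 0.0

    @property
    def valid(self) -> bool:
        return self.objectives is not None

    def genes(self) -> dict:
        return dict(zip(GENE_NAMES, map(float, self.genome)))


def fast_non_dominated_sort(F: np.ndarray) -> list[np.ndarray]:
    """Partition rows of the (n, m) minimization-objective matrix into
    Pareto fronts (rank 0 first)."""
    n = F.shape[0]
    S = [[] for _ in range(n)]
    dominated_count = np.zeros(n, dtype=int)
    fronts = [[]]
    for p in range(n):
        for q in range(n):
            if p == q:
                continue
            if _dominates(F[p], F[q]):
                S[p].append(q)
            elif _dominates(F[q], F[p]):
                dominated_count[p] += 1
        if dominated_count[p] == 0:
            fronts[0].append(p)
    i = 0
    while fronts[i]:
        nxt = []
        for p in fronts[i]:
            for q in S[p]:
                dominated_count[q] -= 1
                if dominated_count[q] == 0:
                    nxt.append(q)
        i += 1
        fronts.append(nxt)
    return [np.array(f, dtype=int) for f in fronts[:-1]]


def _dominates(a: np.ndarray, b: np.ndarray) -> bool:
    return bool(np.all(a <= b) and np.any(a < b))


def crowding_distance(F: np.ndarray) -> np.ndarray:
    """Crowding distance of each row within one front (inf at extremes)."""
    n, m = F.shape
    d = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for k in range(m):
        order = np.argsort(F[:, k])
        span = F[order[-1], k] - F[order[0], k]
        d[order[0]] = d[order[-1]] = np.inf
        if span == 0:
            continue
        d[order[1:-1]] += (F[order[2:], k] - F[order[:-2], k]) / span
    return d


def sbx_crossover(p1, p2, bounds, rng, eta=ETA_CROSSOVER):
    """Simulated binary crossover (bounded), returning two children."""
    c1, c2 = p1.copy(), p2.copy()
    if rng.random() > P_CROSSOVER:
        return c1, c2
    for k in range(p1.size):
        if rng.random() > 0.5 or p1[k] == p2[k]:
            continue
        lo, hi = bounds[k]
        x1, x2 = sorted((p1[k], p2[k]))
        u = rng.random()
        beta = 1.0 + 2.0 * (x1 - lo) / (x2 - x1)
        alpha = 2.0 - beta ** -(eta + 1.0)
        bq = (
            (u * alpha) ** (1.0 / (eta + 1.0))
            if u <= 1.0 / alpha
            else (1.0 / (2.0 - u * alpha)) ** (1.0 / (eta + 1.0))
        )
        y1 = 0.5 * ((x1 + x2) - bq * (x2 - x1))
        beta = 1.0 + 2.0 * (hi - x2) / (x2 - x1)
        alpha = 2.0 - beta ** -(eta + 1.0)
        bq = (
            (u * alpha) ** (1.0 / (eta + 1.0))
            if u <= 1.0 / alpha
            else (1.0 / (2.0 - u * alpha)) ** (1.0 / (eta + 1.0))
        )
        y2 = 0.5 * ((x1 + x2) + bq * (x2 - x1))
        if rng.random() < 0.5:
            y1, y2 = y2, y1
        c1[k] = np.clip(y1, lo, hi)
        c2[k] = np.clip(y2, lo, hi)
    return c1, c2


def polynomial_mutation(g, bounds, rng, eta=ETA_MUTATION, p_mut=P_MUTATION):
    """Bounded polynomial mutation applied gene-wise with probability p_mut."""
    out = g.copy()
    for k in range(g.size):
        if rng.random() >= p_mut:
            continue
        lo, hi = bounds[k]
        span = hi - lo
        x = out[k]
        u = rng.random()
        if u < 0.5:
            delta = (2.0 * u + (1.0 - 2.0 * u)
                     * (1.0 - (x - lo) / span) ** (eta + 1.0)) ** (1.0 / (eta + 1.0)) - 1.0
        else:
            delta = 1.0 - (2.0 * (1.0 - u) + 2.0 * (u - 0.5)
                           * (1.0 - (hi - x) / span) ** (eta + 1.0)) ** (1.0 / (eta + 1.0))
        out[k] = np.clip(x + delta * span, lo, hi)
    return out


def _assign_rank_crowding(pop: list[Individual]) -> None:
    F = np.array([ind.objectives for ind in pop], dtype=float)
    fronts = fast_non_dominated_sort(F)
    for rank, front in enumerate(fronts):
        cd = crowding_distance(F[front])
        for idx, c in zip(front, cd):
            pop[idx].rank = rank
            pop[idx].crowding = float(c)


def _truncate(pop: list[Individual], n_pop: int) -> list[Individual]:
    """Elitist survival: fill by rank, break the last front by crowding."""
    _assign_rank_crowding(pop)
    pop_sorted = sorted(pop, key=lambda ind: (ind.rank, -ind.crowding))
    return pop_sorted[:n_pop]


def _tournament(pop: list[Individual], rng) -> Individual:
    best = None
    for _ in range(TOURNAMENT_SIZE):
        cand = pop[rng.integers(len(pop))]
        if (
            best is None
            or cand.rank < best.rank
            or (cand.rank == best.rank and cand.crowding > best.crowding)
        ):
            best = cand
    return best


def pareto_archive_update(
    archive: list[Individual], new: list[Individual]
) -> list[Individual]:
    """Merge new individuals into a globally non-dominated archive."""
    merged = archive + [ind for ind in new if ind.valid]
    if not merged:
        return []
    F = np.array([ind.objectives for ind in merged], dtype=float)
    keep = fast_non_dominated_sort(F)[0]
    return [merged[i] for i in keep]


def nsga2_evolve(
    evaluate,
    bounds: np.ndarray,
    n_init: int = 320,
    n_pop: int = 80,
    n_gen: int = 20,
    seed: int = 0,
    callback=None,
    return_archive: bool = False,
):
    """Run NSGA-II with a black-box evaluation function.

    ``evaluate(genome, index)`` returns a tuple of minimization objectives,
    or an Individual, or None for an invalid candidate.  Returns the final
    population sorted by (rank, -crowding); the rank-0 subset is the Pareto
    front estimate.  With ``return_archive=True`` a (population, archive)
    pair is returned, where the archive holds every individual that was
    never dominated by any other evaluated one.  Fully deterministic for a
    fixed seed; ``callback(gen, population, archive)`` runs once per
    generation.
    """
    rng = np.random.default_rng(seed)
    bounds = np.asarray(bounds, dtype=float)
    counter = 0

    def _eval(genome, gen):
        nonlocal counter
        res = evaluate(genome, counter)
        counter += 1
        if isinstance(res, Individual):
            res.generation = gen
            return res
        return Individual(genome=genome, objectives=res, generation=gen)

    pop = []
    for _ in range(n_init):
        g = rng.uniform(bounds[:, 0], bounds[:, 1])
        pop.append(_eval(g, 0))
    pop = [ind for ind in pop if ind.valid]
    if not pop:
        raise RuntimeError("no valid individual in the initial population")
    archive = pareto_archive_update([], pop)
    pop = _truncate(pop, n_pop)

    for gen in range(1, n_gen + 1):
        offspring = []
        while len(offspring) < n_pop:
            p1 = _tournament(pop, rng)
            p2 = _tournament(pop, rng)
            c1, c2 = sbx_crossover(p1.genome, p2.genome, bounds, rng)
            for c in (c1, c2):
                if len(offspring) >= n_pop:
                    break
                c = polynomial_mutation(c, bounds, rng)
                offspring.append(_eval(c, gen))
        merged = pop + [ind for ind in offspring if ind.valid]
        if not merged:
            raise RuntimeError(f"generation {gen}: all individuals invalid")
        archive = pareto_archive_update(archive, offspring)
        pop = _truncate(merged, n_pop)
        if callback is not None:
            callback(gen, pop, archive)
    return (pop, archive) if return_archive else pop


@dataclass
class FitTargets:
    """Empirical fitting targets: per-subject FC matrices, optional
    per-subject FCD matrices, and an EEG power spectrum."""

    fcs: list = field(default_factory=list)
    fcds: list = field(default_factory=list)
    spectrum_freqs: np.ndarray | None = None
    spectrum_power: np.ndarray | None = None

    @property
    def has_spectrum(self) -> bool:
        return self.spectrum_freqs is not None


#: evaluation modes: fMRI-only (2-D fitness) or fMRI+EEG (3-D fitness) with
#: median-rate filtering for tonic-firing (up-to-down) solutions
MODES = ("fmri_only", "fmri_eeg_up2down", "fmri_eeg_down2up")


def stagewise_evaluate(
    genes: dict,
    connectome: Connectome,
    table,
    targets: FitTargets,
    mode: str = "fmri_eeg_up2down",
    base_params: NodeParams | None = None,
    seed: int = 0,
    duration: float = 720_000.0,
    screen_duration: float = 10_000.0,
    dt: float = 0.1,
    rec_dt: float = 10.0,
) -> FitnessVector:
    """Two-stage evaluation of one parameter set.

    Stage 1 simulates ``screen_duration`` ms (1 s transient): the run is
    invalid if no region's rate exceeds 10 Hz, and -- in up-to-down mode --
    if the median rate over all nodes and times falls outside [1, 15] Hz.
    Stage 2 runs the full-length simulation and computes the fitness vector.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    base = base_params or NodeParams()
    K_gl = float(genes["K_gl"])
    p = base.with_(**{k: float(v) for k, v in genes.items() if k != "K_gl"})

    try:
        screen = simulate_network(
            connectome, p, table, K_gl=K_gl, duration=screen_duration - 1000.0,
            dt=dt, seed=seed, transient=1000.0, rec_dt=rec_dt,
        )
    except FloatingPointError:
        return FitnessVector(valid=False)
    if screen.rE.max() <= 10.0:
        return FitnessVector(valid=False)
    if mode == "fmri_eeg_up2down":
        med = float(np.median(screen.rE))
        if med < 1.0 or med > 15.0:
            return FitnessVector(valid=False)

    try:
        trace = simulate_network(
            connectome, p, table, K_gl=K_gl, duration=duration, dt=dt,
            seed=seed + 1, transient=1000.0, rec_dt=rec_dt,
        )
    except FloatingPointError:
        return FitnessVector(valid=False)
    bold = bold_transform(trace.rE, dt=rec_dt)
    fc = compute_fc(bold)
    fcv = fc_similarity(fc, targets.fcs) if targets.fcs else np.nan
    try:
        fcd = compute_fcd(bold)
        ksv = fcd_distance(fcd, targets.fcds) if targets.fcds else np.nan
    except ValueError:
        ksv = np.nan
    spec = np.nan
    if mode != "fmri_only" and targets.has_spectrum:
        spec = spectrum_fit(
            trace.mean_rE, dt, targets.spectrum_freqs, targets.spectrum_power,
            last_s=min(60.0, trace.mean_rE.size * dt / 1000.0),
        )
    fv = FitnessVector(fc_corr=fcv, fcd_ks=ksv, spec_corr=spec, valid=True)
    needed = [fcv, ksv] + ([spec] if mode != "fmri_only" else [])
    if not np.all(np.isfinite(needed)):
        fv.valid = False
    return fv


def evolve_brain_model(
    connectome: Connectome,
    table,
    targets: FitTargets,
    mode: str = "fmri_eeg_up2down",
    n_init: int = 640,
    n_pop: int = 160,
    n_gen: int = 50,
    seed: int = 0,
    duration: float = 720_000.0,
    base_params: NodeParams | None = None,
    callback=None,
    **eval_kw,
) -> list[Individual]:
    """NSGA-II search over the six free model parameters (see GENE_NAMES).

    Every candidate is evaluated independently with a seed derived from the
    master seed and its global index, so results do not depend on
    evaluation order.  All sizes are scalable down for desk-scale runs.
    """
    use_spec = mode != "fmri_only"

    def _evaluate(genome, index):
        genes = dict(zip(GENE_NAMES, genome))
        fv = stagewise_evaluate(
            genes, connectome, table, targets, mode=mode,
            base_params=base_params, seed=seed * 1_000 + index * 2,
            duration=duration, **eval_kw,
        )
        ind = Individual(genome=genome, fitness=fv)
        if fv.valid:
            ind.objectives = fv.as_minimization(use_spectrum=use_spec)
        return ind

    return nsga2_evolve(
        _evaluate, GENE_BOUNDS, n_init=n_init, n_pop=n_pop, n_gen=n_gen,
        seed=seed, callback=callback,
    )


def score_individuals(pop: list[Individual]) -> np.ndarray:
    """Scalar post-hoc score: equal-weight sum of objectives after
    normalizing each to [0, 1] over the population (higher is better).
    Used to rank a Pareto set, e.g. to pick a reference model."""
    F = np.array([ind.objectives for ind in pop if ind.valid], dtype=float)
    lo, hi = F.min(axis=0), F.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return 1.0 - ((F - lo) / span).mean(axis=1)
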