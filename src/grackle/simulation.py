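"""Synthetic cohorts: modular GRN, stochastic expression, planted subgroups.

The benchmark cohort emulates the structure of a regulatory-network-driven
expression study: a directed TF -> gene network with planted community
structure, stochastic single-sample expression profiles driven by that
network, subgroup-specific upregulation of whole network modules, additive
background noise on off-module genes, and per-gene min-max scaling.

The expression engine is a discrete stochastic birth-death simulator with
regulator-gated transcription:

* each gene's RNA count gains ``Poisson(rate)`` molecules per iteration,
  where the rate is ``transcription_bound`` when at least one of its
  regulators currently exerts influence (its TF protein is present and the
  influence survived this iteration's stochastic unbinding draw) and
  ``transcription_basal`` otherwise;
* RNA decays by ``Binomial(count, rna_degradation)`` per iteration;
* TF proteins are translated from their own RNA at ``translation`` per
  molecule and decay at ``protein_degradation``.

For an unregulated gene this is a birth-death chain with stationary mean
``transcription_basal / rna_degradation``, which anchors the engine's
calibration.  Per sample the iteration count is drawn uniformly from
``iter_range`` (default 400-600) and the final RNA counts of three
replicate runs are averaged, mimicking profiles captured at arbitrary
points of the cell cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graphs import GeneRegulatoryNetwork

logger = logging.getLogger("grackle")

#: hard cap on molecule counts; beyond this the rates are implausible
OVERFLOW_LIMIT = 1e9

DEFAULT_ITER_RANGE = (400, 600)
DEFAULT_N_REPLICATES = 3
DEFAULT_N_GENES = 400
DEFAULT_N_SAMPLES = 100
DEFAULT_N_SUBGROUPS = 5
DEFAULT_UPREGULATION = 2.0
#: background noise sd as a fraction of the per-gene value range; chosen so
#: spurious background upregulation is commensurate with the module
#: upregulation it mimics
DEFAULT_NOISE_SD_FRACTION = 0.5


@dataclass
class SimulatorRates:
    """Per-iteration event rates of the stochastic expression engine.

    Defaults follow the six standard delayed-event rates in printed
    order: translation 0.002, RNA degradation 0.005, protein degradation
    0.005, TF unbinding 0.005, transcription 0.01 (basal) / 0.02 (bound).
    """

    translation: float = 0.002
    rna_degradation: float = 0.005
    protein_degradation: float = 0.005
    tf_unbinding: float = 0.005
    transcription_basal: float = 0.01
    transcription_bound: float = 0.02

    def __post_init__(self) -> None:
        for name in (
            "translation", "rna_degradation", "protein_degradation",
            "tf_unbinding", "transcription_basal", "transcription_bound",
        ):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"rate {name} must be finite and > 0, got {v}")


@dataclass
class SimulatedCohort:
    """A complete synthetic benchmark cohort."""

    grn: GeneRegulatoryNetwork
    modules: dict[str, int]  # gene id -> module id
    subgroup_labels: list[str]  # per sample; module id as str, or "background"
    perturbed_modules: list[int]
    expression_raw: np.ndarray
    expression_perturbed: np.ndarray
    expression_final: np.ndarray
    noise_fraction: float
    seed: int
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Network generation and module detection
# ---------------------------------------------------------------------------

def generate_random_grn(
    n_genes: int = DEFAULT_N_GENES,
    n_tfs: int = 80,
    target_modules: int = DEFAULT_N_SUBGROUPS,
    within_p: float = 0.5,
    between_p: float = 0.002,
    triangle_boost: float = 0.0,
    seed: int = 0,
) -> GeneRegulatoryNetwork:
    """Planted-block directed TF -> gene network.

    Genes are split into ``target_modules`` equal blocks; the first TFs of
    each block act as regulators.  A TF regulates a gene of its own block
    with probability ``within_p`` and a gene of another block with
    probability ``between_p`` — the within/between contrast controls
    modularity.  ``triangle_boost`` closes open TF-TF-gene triads with the
    given probability to raise transitivity.  Edge weights are drawn
    uniform on (1, 2] so the network is already above the binarization
    threshold.
    """
    if n_tfs >= n_genes:
        raise ValueError("n_tfs must be < n_genes")
    if not (0 <= between_p < within_p <= 1):
        raise ValueError("need 0 <= between_p < within_p <= 1")
    block_sizes = np.full(target_modules, n_genes // target_modules)
    block_sizes[: n_genes % target_modules] += 1
    if block_sizes.min() < 3:
        raise ValueError(
            f"a planted module would have {block_sizes.min()} < 3 genes"
        )
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    block_of = np.repeat(np.arange(target_modules), block_sizes)
    # spread TFs round-robin over blocks so every module has regulators
    tfs_per_block = [[] for _ in range(target_modules)]
    block_members = [np.where(block_of == b)[0] for b in range(target_modules)]
    for t in range(n_tfs):
        b = t % target_modules
        members = block_members[b]
        tfs_per_block[b].append(int(members[t // target_modules % len(members)]))
    tf_idx = sorted({t for blk in tfs_per_block for t in blk})

    edges: list[tuple[str, str, float]] = []
    seen: set[tuple[int, int]] = set()

    def add_edge(i: int, j: int) -> None:
        if i == j or (i, j) in seen:
            return
        seen.add((i, j))
        edges.append((genes[i], genes[j], float(1.0 + rng.random())))

    for b in range(target_modules):
        for t in tfs_per_block[b]:
            for j in block_members[b]:
                if rng.random() < within_p:
                    add_edge(t, int(j))
            for b2 in range(target_modules):
                if b2 == b:
                    continue
                for j in block_members[b2]:
                    if rng.random() < between_p:
                        add_edge(t, int(j))
    # close open triads t1 -> g, t2 -> g with a t1 -> t2 edge
    if triangle_boost > 0:
        targets_of: dict[int, list[int]] = {}
        for i, j in seen:
            targets_of.setdefault(i, []).append(j)
        for t in list(targets_of):
            for j in targets_of[t]:
                if j in targets_of and rng.random() < triangle_boost:
                    for j2 in targets_of[j]:
                        if (t, j2) not in seen and rng.random() < triangle_boost:
                            add_edge(t, j2)
    if not edges:
        raise ValueError("generated network has no edges; raise within_p")
    logger.info(
        "generate_random_grn: %d genes, %d TFs, %d edges", n_genes, len(tf_idx),
        len(edges),
    )
    return GeneRegulatoryNetwork(nodes=genes, edges=edges, directed=True)


def detect_modules(grn: GeneRegulatoryNetwork, seed: int = 0) -> dict[str, int]:
    """Louvain community detection on the undirected projection of the GRN.

    Returns a module id per node; disconnected singletons become their own
    modules (logged).
    """
    if grn.n_nodes == 0:
        raise ValueError("empty network")
    g = nx.Graph()
    g.add_nodes_from(grn.nodes)
    g.add_edges_from((s, t) for s, t, _ in grn.edges if s != t)
    communities = nx.community.louvain_communities(g, seed=seed)
    # deterministic module numbering: sort communities by their smallest node
    communities = sorted(communities, key=lambda c: min(c))
    modules: dict[str, int] = {}
    n_singletons = 0
    for mid, comm in enumerate(communities):
        if len(comm) == 1:
            n_singletons += 1
        for node in comm:
            modules[node] = mid
    if n_singletons:
        logger.info("detect_modules: %d singleton modules", n_singletons)
    return modules


# ---------------------------------------------------------------------------
# Stochastic expression engine
# ---------------------------------------------------------------------------

def simulate_expression(
    grn: GeneRegulatoryNetwork,
    rates: SimulatorRates | None = None,
    n_samples: int = DEFAULT_N_SAMPLES,
    iter_range: tuple[int, int] = DEFAULT_ITER_RANGE,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a samples x genes matrix of stochastic RNA counts.

    Each sample draws an iteration count uniformly from ``iter_range``
    and averages ``n_replicates`` independent runs of the engine
    described in the module docstring.
    """
    if rates is None:
        rates = SimulatorRates()
    if iter_range[0] < 1 or iter_range[1] < iter_range[0]:
        raise ValueError(f"invalid iter_range {iter_range}")
    if not grn.is_binary():
        raise ValueError("simulate_expression requires a binarized GRN")
    rng = np.random.default_rng(seed)
    n_genes = grn.n_nodes
    gene_index = {g: i for i, g in enumerate(grn.nodes)}
    edge_src = np.array([gene_index[s] for s, _, _ in grn.edges], dtype=np.intp)
    edge_tgt = np.array([gene_index[t] for _, t, _ in grn.edges], dtype=np.intp)
    tf_nodes = np.unique(edge_src)
    n_edges = len(edge_src)

    # all sample replicates advance in lockstep; each sample's state is read
    # off at its own iteration count, so the engine stays one vectorized loop
    n_iters = rng.integers(iter_range[0], iter_range[1] + 1, size=n_samples)
    B = n_samples * n_replicates  # one chain per (sample, replicate)
    rna = np.zeros((B, n_genes), dtype=np.int64)
    protein = np.zeros((B, n_genes), dtype=np.int64)
    out = np.zeros((B, n_genes), dtype=np.int64)
    stop_at = np.repeat(n_iters, n_replicates)
    for t in range(1, int(n_iters.max()) + 1):
        if n_edges:
            # regulator influence: TF protein present and no unbinding event
            active = (protein[:, edge_src] > 0) & (
                rng.random((B, n_edges)) >= rates.tf_unbinding
            )
            bound = np.zeros((B, n_genes), dtype=bool)
            np.logical_or.at(bound, (slice(None), edge_tgt), active)
            rate = np.where(
                bound, rates.transcription_bound, rates.transcription_basal
            )
        else:
            rate = np.full((B, n_genes), rates.transcription_basal)
        rna += rng.poisson(rate)
        rna -= rng.binomial(rna, rates.rna_degradation)
        protein[:, tf_nodes] += rng.poisson(rates.translation * rna[:, tf_nodes])
        protein -= rng.binomial(protein, rates.protein_degradation)
        done = stop_at == t
        if done.any():
            out[done] = rna[done]
    if out.max(initial=0) > OVERFLOW_LIMIT:
        raise OverflowError("RNA counts exceeded 1e9; rescale the simulator rates")
    return out.reshape(n_samples, n_replicates, n_genes).mean(axis=1)


# ---------------------------------------------------------------------------
# Perturbation, noise, scaling
# ---------------------------------------------------------------------------

def perturb_and_label(
    expr: np.ndarray,
    modules: dict[str, int],
    gene_ids: list[str],
    n_subgroups: int = DEFAULT_N_SUBGROUPS,
    samples_per_subgroup: int | None = None,
    upregulation_factor: float = DEFAULT_UPREGULATION,
    seed: int = 0,
) -> tuple[np.ndarray, list[str], list[int]]:
    """Upregulate one network module per sample subgroup.

    Randomly selects ``n_subgroups`` modules with >= 3 genes, splits off
    ``samples_per_subgroup`` samples for each (default: an equal share of
    all samples), and multiplies the module genes' values by
    ``upregulation_factor`` within the matching subgroup.  Returns the
    perturbed matrix, per-sample labels (the perturbed module id as a
    string, or ``"background"``) and the list of perturbed module ids.
    """
    if upregulation_factor < 1:
        raise ValueError("upregulation_factor must be >= 1")
    n_samples = expr.shape[0]
    rng = np.random.default_rng(seed)
    module_ids = sorted({m for m in modules.values()})
    sizes = {m: sum(1 for g in gene_ids if modules.get(g) == m) for m in module_ids}
    eligible = [m for m in module_ids if sizes[m] >= 3]
    if n_subgroups > len(eligible):
        raise ValueError(
            f"n_subgroups={n_subgroups} exceeds the {len(eligible)} modules "
            "with >= 3 genes"
        )
    chosen = sorted(rng.choice(eligible, size=n_subgroups, replace=False).tolist())
    if samples_per_subgroup is None:
        samples_per_subgroup = n_samples // n_subgroups
    if samples_per_subgroup * n_subgroups > n_samples:
        raise ValueError("subgroup assignment exceeds the number of samples")
    order = rng.permutation(n_samples)
    labels = ["background"] * n_samples
    out = expr.astype(float).copy()
    gene_arr = np.asarray(gene_ids)
    for g_idx, mod in enumerate(chosen):
        block = order[g_idx * samples_per_subgroup:(g_idx + 1) * samples_per_subgroup]
        cols = np.array([modules.get(g) == mod for g in gene_arr])
        out[np.ix_(block, cols)] *= upregulation_factor
        for s in block:
            labels[s] = str(mod)
    return out, labels, chosen


def add_background_noise(
    expr: np.ndarray,
    modules: dict[str, int],
    gene_ids: list[str],
    perturbed_modules: list[int],
    noise_fraction: float,
    noise_sd: np.ndarray | float | None = None,
    sample_labels: list[str] | None = None,
    mode: str = "per_sample",
    seed: int = 0,
) -> np.ndarray:
    """Additive half-Gaussian upregulation noise on background genes.

    ``mode='per_sample'`` (default): for each sample, a fraction
    ``noise_fraction`` of the genes *outside that sample's own perturbed
    module* is drawn independently and upregulated by ``|N(0, sd)|`` —
    so as the fraction grows, samples of one subgroup increasingly show
    spurious activation of other subgroups' modules, which is what makes
    the noise sweep erode label-free factorizations.  Requires
    ``sample_labels`` (a sample's module is ``int(label)``; background
    samples have no exclusion).

    ``mode='per_cohort'``: a single draw of
    ``floor(noise_fraction * n)`` genes among those outside *every*
    perturbed module; perturbed-module genes are never touched.

    ``noise_sd`` defaults to 0.5 of each gene's pre-noise value range.
    """
    if not 0 <= noise_fraction <= 1:
        raise ValueError(f"noise_fraction must be in [0, 1], got {noise_fraction}")
    if mode not in ("per_sample", "per_cohort"):
        raise ValueError(f"unknown noise mode {mode!r}")
    out = expr.astype(float).copy()
    if noise_fraction == 0:
        return out
    rng = np.random.default_rng(seed)
    n_samples, n_genes = out.shape
    gene_module = np.array(
        [modules.get(g, -1) for g in gene_ids], dtype=int
    )
    span = out.max(axis=0) - out.min(axis=0)
    if noise_sd is None:
        sd = DEFAULT_NOISE_SD_FRACTION * span
    else:
        sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), (n_genes,))

    if mode == "per_cohort":
        off_idx = np.where(~np.isin(gene_module, perturbed_modules))[0]
        n_pick = int(np.floor(noise_fraction * len(off_idx)))
        if n_pick == 0:
            return out
        picked = rng.choice(off_idx, size=n_pick, replace=False)
        for j in picked:
            if sd[j] > 0:
                out[:, j] += np.abs(rng.normal(0.0, sd[j], size=n_samples))
        return out

    if sample_labels is None:
        raise ValueError("per_sample noise requires sample_labels")
    for i in range(n_samples):
        label = str(sample_labels[i])
        own = int(label) if label != "background" else None
        eligible = np.where(gene_module != own)[0] if own is not None else np.arange(n_genes)
        n_pick = int(np.floor(noise_fraction * len(eligible)))
        if n_pick == 0:
            continue
        picked = rng.choice(eligible, size=n_pick, replace=False)
        boost = np.abs(rng.normal(0.0, 1.0, size=n_pick)) * sd[picked]
        out[i, picked] += boost
    return out


def min_max_scale(expr: np.ndarray, axis: str = "gene") -> np.ndarray:
    """Per-gene (column) min-max scaling to [0, 1]; constant genes map to 0."""
    X = np.asarray(expr, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("expression contains non-finite values")
    ax = 0 if axis == "gene" else 1
    lo = X.min(axis=ax, keepdims=True)
    hi = X.max(axis=ax, keepdims=True)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(span > 0, (X - lo) / np.where(span > 0, span, 1.0), 0.0)
    return out


# ---------------------------------------------------------------------------
# End-to-end cohort
# ---------------------------------------------------------------------------

def simulate_cohort(
    n_genes: int = DEFAULT_N_GENES,
    n_samples: int = DEFAULT_N_SAMPLES,
    n_subgroups: int = DEFAULT_N_SUBGROUPS,
    target_modules: int | None = None,
    noise_fraction: float = 0.0,
    upregulation_factor: float = DEFAULT_UPREGULATION,
    within_p: float = 0.5,
    between_p: float = 0.002,
    triangle_boost: float = 0.0,
    rates: SimulatorRates | None = None,
    iter_range: tuple[int, int] = DEFAULT_ITER_RANGE,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int = 0,
) -> SimulatedCohort:
    """Generate a full benchmark cohort as a pure function of the seed.

    Pipeline: planted-block GRN -> Louvain modules -> stochastic
    expression -> subgroup perturbation -> background noise -> per-gene
    min-max scaling.  Sub-stage seeds are derived from ``seed`` by fixed
    offsets so every stage is reproducible.

    The network plants more modules than there are subgroups (default
    twice as many), and the perturbed ones are drawn at random among the
    detected communities; the remaining modules supply the off-module
    genes that background noise acts on.
    """
    from .graphs import threshold_grn

    if target_modules is None:
        target_modules = 2 * n_subgroups
    grn = generate_random_grn(
        n_genes=n_genes, n_tfs=max(2 * n_subgroups, n_genes // 5),
        target_modules=target_modules, within_p=within_p, between_p=between_p,
        triangle_boost=triangle_boost, seed=seed,
    )
    grn = threshold_grn(grn, cutoff=1.0)  # generator weights lie in (1, 2]
    modules = detect_modules(grn, seed=seed)
    raw = simulate_expression(
        grn, rates=rates, n_samples=n_samples, iter_range=iter_range,
        n_replicates=n_replicates, seed=seed + 1,
    )
    perturbed, labels, chosen = perturb_and_label(
        raw, modules, grn.nodes, n_subgroups=n_subgroups,
        upregulation_factor=upregulation_factor, seed=seed + 2,
    )
    noisy = add_background_noise(
        perturbed, modules, grn.nodes, chosen, noise_fraction,
        sample_labels=labels, seed=seed + 3,
    )
    final = min_max_scale(noisy)
    return SimulatedCohort(
        grn=grn, modules=modules, subgroup_labels=labels,
        perturbed_modules=chosen, expression_raw=raw,
        expression_perturbed=perturbed, expression_final=final,
        noise_fraction=noise_fraction, seed=seed,
        gene_ids=list(grn.nodes),
        sample_ids=[f"s{i:04d}" for i in range(n_samples)],
    )
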