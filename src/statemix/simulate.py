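"""Synthetic single-cell data and pseudobulk with held-out-cells validation.

The generator emulates the benchmark design used to score references:
single cells are drawn from known state profiles, then split in half so the
reference is built from one set of cells while the pseudobulk mixtures are
assembled from the *other* — no information flows from reference
construction into bulk simulation, mimicking the real situation where the
reference comes from a different study than the bulk cohort.

Generative steps, all driven by one seed:

1. per-type base gene profile ~ Dirichlet(profile_separation) — small
   concentrations give sparse, well-separated type profiles;
2. per-state profile ~ Dirichlet(state_concentration · base) — states jitter
   around their type's base;
3. per-cell profile ~ Dirichlet(noise · state profile), counts ~
   Multinomial(cell_depth, cell profile) — within-state heterogeneity;
4. cells of each state split 50/50 into a reference half and a simulation
   half (disjoint cell ids);
5. per-sample type fractions ~ Dirichlet(fraction_prior), divided equally
   among the type's states; pseudobulk column ~ Multinomial(reads_per_bulk,
   mixture of the simulation half's pooled state profiles).

An optional per-gene log-normal factor applied to the reference half
(`shift_reference`) emulates platform differences between reference and
bulk; optional negative-binomial overdispersion stresses the model
off-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .model import BulkMatrix
from .reference import SingleCellCounts


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic benchmark dataset.

    Defaults correspond to a moderately noisy 8-type tumour-like benchmark:
    1000 genes, 2 states per type, 200 cells per state (100 per half),
    100 pseudobulk samples of 100k reads with flat Dirichlet type fractions.
    """

    n_genes: int = 1000
    n_types: int = 8
    states_per_type: int = 2
    n_cells_per_state: int = 200
    n_bulk_samples: int = 100
    reads_per_bulk: int = 100_000
    fraction_prior: float = 1.0
    profile_separation: float = 0.1
    state_concentration: float = 5000.0
    noise: float = 1000.0
    cell_depth: int = 2000
    shift_reference: float = 0.0
    overdispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes", "n_types", "states_per_type", "n_cells_per_state",
            "n_bulk_samples", "reads_per_bulk", "cell_depth",
        ):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be positive")
        if self.n_cells_per_state < 2:
            raise ParameterError(
                "n_cells_per_state must be >= 2 to split reference/simulation halves"
            )
        for name in ("fraction_prior", "profile_separation",
                     "state_concentration", "noise"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.shift_reference < 0 or self.overdispersion < 0:
            raise ParameterError("shift_reference and overdispersion must be >= 0")


@dataclass
class SyntheticDataset:
    """Ground truth plus the generated single-cell halves and pseudobulk."""

    config: SimulationConfig
    true_type_fractions: np.ndarray  # sample × type
    true_state_fractions: np.ndarray  # sample × state
    type_ids: list[str]
    state_ids: list[str]
    state_to_type: dict[str, str]
    state_profiles: np.ndarray  # gene × state ground-truth probabilities
    sc_reference_half: SingleCellCounts
    sc_simulation_half: SingleCellCounts
    pseudobulk: BulkMatrix
    sim_half_profiles: np.ndarray = field(repr=False, default=None)


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate one dataset under ``cfg``; bit-reproducible under its seed."""
    rng = np.random.default_rng(cfg.seed)
    G = cfg.n_genes
    type_ids = [f"T{k + 1}" for k in range(cfg.n_types)]
    state_ids = [
        f"{t}.s{j + 1}" for t in type_ids for j in range(cfg.states_per_type)
    ]
    state_to_type = {s: s.split(".")[0] for s in state_ids}
    S = len(state_ids)

    base = rng.dirichlet(np.full(G, cfg.profile_separation), size=cfg.n_types)
    profiles = np.empty((G, S))
    for j, s in enumerate(state_ids):
        k = type_ids.index(state_to_type[s])
        conc = cfg.state_concentration * base[k] + 1e-12
        profiles[:, j] = rng.dirichlet(conc)

    # per-state cells; even split into disjoint halves
    half = cfg.n_cells_per_state // 2
    ref_cols, sim_cols = [], []
    ref_states, sim_states = [], []
    ref_ids, sim_ids = [], []
    for j, s in enumerate(state_ids):
        for c in range(cfg.n_cells_per_state):
            cell_p = rng.dirichlet(cfg.noise * profiles[:, j] + 1e-12)
            counts = rng.multinomial(cfg.cell_depth, cell_p).astype(float)
            cid = f"{s}.c{c + 1}"
            if c < half:
                ref_cols.append(counts)
                ref_states.append(s)
                ref_ids.append(cid)
            else:
                sim_cols.append(counts)
                sim_states.append(s)
                sim_ids.append(cid)

    gene_ids = [f"g{i + 1}" for i in range(G)]
    ref_counts = np.column_stack(ref_cols)
    if cfg.shift_reference > 0:
        factors = rng.lognormal(mean=0.0, sigma=cfg.shift_reference, size=G)
        ref_counts = ref_counts * factors[:, None]
    sc_ref = SingleCellCounts(
        counts=ref_counts,
        gene_ids=gene_ids,
        cell_type_labels=[state_to_type[s] for s in ref_states],
        cell_state_labels=list(ref_states),
        cell_ids=ref_ids,
    )
    sc_sim = SingleCellCounts(
        counts=np.column_stack(sim_cols),
        gene_ids=gene_ids,
        cell_type_labels=[state_to_type[s] for s in sim_states],
        cell_state_labels=list(sim_states),
        cell_ids=sim_ids,
    )

    # pooled simulation-half profiles are the mixing components of the bulk
    sim_states_arr = np.asarray(sim_states)
    sim_profiles = np.empty((G, S))
    for j, s in enumerate(state_ids):
        pooled = sc_sim.counts[:, sim_states_arr == s].sum(axis=1)
        tot = pooled.sum()
        sim_profiles[:, j] = pooled / tot if tot > 0 else 1.0 / G

    theta_type = rng.dirichlet(
        np.full(cfg.n_types, cfg.fraction_prior), size=cfg.n_bulk_samples
    )
    theta_state = np.repeat(theta_type, cfg.states_per_type, axis=1) / cfg.states_per_type

    X = np.empty((G, cfg.n_bulk_samples))
    for n in range(cfg.n_bulk_samples):
        p = sim_profiles @ theta_state[n]
        p = p / p.sum()
        if cfg.overdispersion > 0:
            # gamma-multinomial: log-normal-free NB-style extra variance
            w = rng.gamma(1.0 / cfg.overdispersion, cfg.overdispersion, size=G)
            p = p * w
            p = p / p.sum()
        X[:, n] = rng.multinomial(cfg.reads_per_bulk, p)

    pseudobulk = BulkMatrix(
        X=X,
        gene_ids=gene_ids,
        sample_ids=[f"bulk{n + 1}" for n in range(cfg.n_bulk_samples)],
    )
    return SyntheticDataset(
        config=cfg,
        true_type_fractions=theta_type,
        true_state_fractions=theta_state,
        type_ids=type_ids,
        state_ids=state_ids,
        state_to_type=state_to_type,
        state_profiles=profiles,
        sc_reference_half=sc_ref,
        sc_simulation_half=sc_sim,
        pseudobulk=pseudobulk,
        sim_half_profiles=sim_profiles,
    )


def fixture_small(seed: int = 0) -> SyntheticDataset:
    """Deterministic tiny dataset for tests and documentation.

    50 genes, 3 types × 2 states, 20 cells per state, 20 pseudobulk samples
    of 10k reads.
    """
    cfg = SimulationConfig(
        n_genes=50,
        n_types=3,
        states_per_type=2,
        n_cells_per_state=20,
        n_bulk_samples=20,
        reads_per_bulk=10_000,
        profile_separation=0.5,
        cell_depth=1000,
        seed=seed,
    )
    return simulate_dataset(cfg)
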