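"""Synthetic miRNA-disease networks with planted low-rank structure.

The generator draws nonnegative latent factors U (miRNAs x rank) and
V (diseases x rank), so each miRNA and disease has a latent "profile";
miRNAs in the same family share their profile with a configurable
coherence probability.  The association matrix thresholds the latent
score P = U V^T at the quantile matching the target density and then
flips each entry independently with a small noise probability.  The
functional and semantic similarity matrices handed to the pipeline are
cosines of the latent profiles, so they are informative about — but not
identical to — the observable network, mimicking how externally derived
similarity scores relate to real association data.

Because the factors are nonnegative (absolute-valued normal draws) the
cosine similarities land in [0, 1] without any affine rescaling.  The
pre-threshold P is returned as ground truth for rank-correlation checks.
Everything is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .datatypes import AssociationMatrix, FamilyAssignment, SimilarityMatrix

__all__ = ["SynthConfig", "generate_network", "generate_lowrank_sparse"]


@dataclass
class SynthConfig:
    """Generator parameters; defaults define the standard test network."""

    m: int = 40
    n: int = 25
    rank: int = 3
    density: float = 0.12
    n_families: int = 8
    family_coherence: float = 0.7
    noise_flip: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rank > min(self.m, self.n):
            raise ValueError("rank must not exceed min(m, n)")
        if not 0 < self.density < 1:
            raise ValueError("density must lie in (0, 1)")
        if self.density * self.m * self.n < 2:
            raise ValueError("density too low: expected knowns < 2")
        if not 0 <= self.family_coherence <= 1:
            raise ValueError("family_coherence must lie in [0, 1]")
        if not 0 <= self.noise_flip < 1:
            raise ValueError("noise_flip must lie in [0, 1)")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def _cosine_unit_diag(factors: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(factors, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = factors / safe[:, None]
    sim = unit @ unit.T
    sim = (sim + sim.T) / 2.0
    np.clip(sim, 0.0, 1.0, out=sim)
    np.fill_diagonal(sim, 1.0)
    return sim


def generate_network(
    config: SynthConfig | None = None,
) -> tuple[AssociationMatrix, SimilarityMatrix, SimilarityMatrix, FamilyAssignment, np.ndarray]:
    """Generate (associations, functional sim, semantic sim, families, ground truth P)."""
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed)

    mirna_ids = [f"mir-{i + 1:03d}" for i in range(cfg.m)]
    disease_ids = [f"disease-{j + 1:03d}" for j in range(cfg.n)]
    fam_ids = [f"fam-{k + 1}" for k in range(cfg.n_families)]

    fam_of = rng.integers(0, cfg.n_families, size=cfg.m)
    fam_profiles = np.abs(rng.normal(size=(cfg.n_families, cfg.rank)))
    U = np.abs(rng.normal(size=(cfg.m, cfg.rank)))
    coherent = rng.random(cfg.m) < cfg.family_coherence
    U[coherent] = fam_profiles[fam_of[coherent]]
    V = np.abs(rng.normal(size=(cfg.n, cfg.rank)))

    P = U @ V.T
    threshold = np.quantile(P, 1.0 - cfg.density)
    A = (P > threshold).astype(float)
    if cfg.noise_flip > 0:
        flips = rng.random((cfg.m, cfg.n)) < cfg.noise_flip
        A = np.where(flips, 1.0 - A, A)
    if A.sum() < 1:
        raise ValueError("generated network has no associations; raise density")

    assoc = AssociationMatrix(A, mirna_ids, disease_ids)
    sim_fun = SimilarityMatrix(_cosine_unit_diag(U), mirna_ids, "mirna_functional")
    sim_phe = SimilarityMatrix(_cosine_unit_diag(V), disease_ids, "disease_semantic")
    fams = FamilyAssignment({mirna_ids[i]: fam_ids[fam_of[i]] for i in range(cfg.m)})
    return assoc, sim_fun, sim_phe, fams, P


def generate_lowrank_sparse(
    m: int,
    n: int,
    rank: int,
    spike_fraction: float = 0.05,
    spike_magnitude: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Planted low-rank + sparse test instance: X = R0 + E0.

    R0 is a product of Gaussian factors (rank exact with probability 1);
    E0 places +/-spike_magnitude at round(spike_fraction * m * n)
    uniformly chosen positions.
    """
    if rank > min(m, n):
        raise ValueError("rank must not exceed min(m, n)")
    if spike_fraction < 0:
        raise ValueError("spike_fraction must be nonnegative")
    rng = np.random.default_rng(seed)
    R0 = rng.normal(size=(m, rank)) @ rng.normal(size=(rank, n))
    E0 = np.zeros((m, n))
    n_spikes = int(round(spike_fraction * m * n))
    if n_spikes > 0:
        flat = rng.choice(m * n, size=n_spikes, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_spikes)
        E0.flat[flat] = signs * spike_magnitude
    return R0 + E0, R0, E0
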