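"""Simulation of pathway-structured expression with proportional-hazards survival.

Each pathway carries a latent per-sample activity ``z ~ N(0, 1)``; its member
genes load on ``z`` with mixed-sign weights plus i.i.d. Gaussian noise, so the
coordinated (anti-)correlation structure that an SVD eigengene should recover
is present by construction.  Survival times follow an exponential
proportional-hazards law — hazard = baseline_rate * exp(sum_p beta_p z_p) —
with independent exponential (or administrative) censoring.  The generator
records the exact latent truth used, writes the same file formats the readers
accept, and therefore doubles as the test-fixture factory for every other
module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .io_formats import ExpressionMatrix, GeneSet, PathwayCollection, SurvivalData

__all__ = [
    "PathwaySpec",
    "SimulationConfig",
    "SimulationTruth",
    "generate",
    "preset_scenarios",
]


@dataclass
class PathwaySpec:
    """One simulated pathway: its size, gene loading scale and survival effect.

    ``confounded_with`` mixes another pathway's latent activity into this
    one's (z <- z_own + confounding_weight * z_other), creating correlated
    activities without a direct survival effect unless ``effect_beta`` is
    also nonzero.
    """

    pathway_id: str
    size: int = 25
    loading_scale: float = 1.0
    effect_beta: float = 0.0
    confounded_with: str | None = None
    confounding_weight: float = 0.0


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Defaults emulate a METABRIC-like setting at desk scale: pathways of ~25
    genes whose members split roughly evenly into positively and negatively
    loading transcripts, unit expression noise (per-gene correlation with the
    latent activity ~0.7), an exponential baseline hazard of 1e-3 per day and
    independent censoring tuned to roughly 30% censored observations.
    """

    m_samples: int = 400
    g_background_genes: int = 200
    pathways: list[PathwaySpec] = field(default_factory=list)
    noise_sd: float = 1.0
    baseline_hazard_rate: float = 1e-3
    censoring_rate: float | None = 4.3e-4
    admin_censor_time: float | None = None
    log_space: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.m_samples < 2:
            raise ConfigError("m_samples must be >= 2")
        if self.g_background_genes < 0:
            raise ConfigError("g_background_genes must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.baseline_hazard_rate <= 0:
            raise ConfigError("baseline_hazard_rate must be > 0")
        if self.censoring_rate is not None and self.censoring_rate < 0:
            raise ConfigError("censoring_rate must be >= 0")
        ids = [p.pathway_id for p in self.pathways]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate pathway IDs in simulation config")
        for p in self.pathways:
            if p.size < 1:
                raise ConfigError(f"pathway {p.pathway_id}: size must be >= 1")
            if p.confounded_with is not None and p.confounded_with not in ids:
                raise ConfigError(
                    f"pathway {p.pathway_id}: unknown confounder {p.confounded_with!r}"
                )


@dataclass
class SimulationTruth:
    """Ground truth exactly as used during generation."""

    latent_activity: dict[str, np.ndarray]   # pathway_id -> length-m z
    loadings: dict[str, np.ndarray]          # pathway_id -> length-size w
    true_betas: dict[str, float]
    event_times: np.ndarray                  # uncensored event times
    censoring_times: np.ndarray


def _resolve_latents(config: SimulationConfig, rng: np.random.Generator):
    """Draw each pathway's latent activity, honouring confounding edges."""
    own = {p.pathway_id: rng.standard_normal(config.m_samples) for p in config.pathways}
    spec = {p.pathway_id: p for p in config.pathways}
    resolved: dict[str, np.ndarray] = {}

    def resolve(pid: str, trail: tuple = ()) -> np.ndarray:
        if pid in resolved:
            return resolved[pid]
        if pid in trail:
            raise ConfigError(f"confounding cycle through {pid!r}")
        p = spec[pid]
        z = own[pid].copy()
        if p.confounded_with is not None:
            z = z + p.confounding_weight * resolve(p.confounded_with, trail + (pid,))
        resolved[pid] = z
        return z

    for pid in spec:
        resolve(pid)
    return resolved


def generate(config: SimulationConfig):
    """Simulate one cohort.

    Returns ``(ExpressionMatrix, PathwayCollection, SurvivalData,
    SimulationTruth)``.  The expression matrix is on the standardized-like
    scale unless ``log_space`` is set, in which case values are exponentiated
    (base 2) so the ``preprocess`` log path can be exercised.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.m_samples
    sample_ids = [f"S{i:04d}" for i in range(m)]

    latents = _resolve_latents(config, rng)

    gene_ids: list[str] = []
    blocks: list[np.ndarray] = []
    sets: list[GeneSet] = []
    loadings: dict[str, np.ndarray] = {}
    for p in config.pathways:
        z = latents[p.pathway_id]
        signs = rng.choice([-1.0, 1.0], size=p.size)
        w = signs * p.loading_scale * rng.uniform(0.5, 1.5, size=p.size)
        loadings[p.pathway_id] = w
        noise = rng.standard_normal((p.size, m)) * config.noise_sd
        blocks.append(w[:, None] * z[None, :] + noise)
        members = [f"{p.pathway_id}_g{j}" for j in range(p.size)]
        gene_ids.extend(members)
        sets.append(GeneSet(p.pathway_id, f"simulated pathway {p.pathway_id}", members))
    if config.g_background_genes:
        blocks.append(rng.standard_normal((config.g_background_genes, m)))
        gene_ids.extend(f"BG_g{j}" for j in range(config.g_background_genes))
    values = np.vstack(blocks) if blocks else np.empty((0, m))
    if config.log_space:
        values = np.exp2(values)
    expression = ExpressionMatrix(gene_ids, sample_ids, values)

    log_hazard = np.zeros(m)
    true_betas = {}
    for p in config.pathways:
        true_betas[p.pathway_id] = p.effect_beta
        if p.effect_beta:
            log_hazard += p.effect_beta * latents[p.pathway_id]
    hazard = config.baseline_hazard_rate * np.exp(log_hazard)
    event_times = rng.exponential(1.0 / hazard)

    if config.admin_censor_time is not None:
        censoring = np.full(m, float(config.admin_censor_time))
    elif config.censoring_rate:
        censoring = rng.exponential(1.0 / config.censoring_rate, size=m)
    else:
        censoring = np.full(m, np.inf)
    observed = np.minimum(event_times, censoring)
    event = (event_times <= censoring).astype(int)
    # guard against a zero observed time (probability zero, but time must be > 0)
    observed = np.maximum(observed, np.finfo(float).tiny)
    surv = SurvivalData(sample_ids, observed, event)

    truth = SimulationTruth(latents, loadings, true_betas, event_times, censoring)
    return expression, PathwayCollection(sets), surv, truth


def preset_scenarios(m_samples: int = 400, seed: int = 0) -> dict[str, SimulationConfig]:
    """Named study conditions used throughout the test-bed.

    * ``null`` — 20 pathways, none prognostic; survival independent of
      expression.
    * ``planted`` — one prognostic pathway among 19 nulls.
    * ``confounded`` — pathway DRIVER drives the hazard; pathway INDIRECT is
      correlated with DRIVER but has no direct effect (the pattern where a
      pathway's apparent prognostic power is driven by a confounder such as
      cell proliferation).
    * ``direct_plus_confounder`` — pathway DIRECT carries its own effect on
      top of correlation with DRIVER, so it stays significant after
      adjustment.
    """
    def nulls(n, start=1, size=20):
        return [PathwaySpec(f"NULL{i:02d}", size=size) for i in range(start, start + n)]

    scenarios = {
        "null": SimulationConfig(
            m_samples=m_samples, g_background_genes=100,
            pathways=nulls(20), seed=seed,
        ),
        "planted": SimulationConfig(
            m_samples=m_samples, g_background_genes=100,
            pathways=[PathwaySpec("PLANTED", size=25, effect_beta=1.0)] + nulls(19),
            seed=seed,
        ),
        "confounded": SimulationConfig(
            m_samples=m_samples, g_background_genes=100,
            pathways=[
                PathwaySpec("DRIVER", size=25, effect_beta=1.0),
                PathwaySpec("INDIRECT", size=25, effect_beta=0.0,
                            confounded_with="DRIVER", confounding_weight=1.5),
            ] + nulls(8),
            seed=seed,
        ),
        "direct_plus_confounder": SimulationConfig(
            m_samples=m_samples, g_background_genes=100,
            pathways=[
                PathwaySpec("DRIVER", size=25, effect_beta=1.0),
                PathwaySpec("DIRECT", size=25, effect_beta=0.8,
                            confounded_with="DRIVER", confounding_weight=0.5),
            ] + nulls(8),
            seed=seed,
        ),
    }
    return scenarios
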