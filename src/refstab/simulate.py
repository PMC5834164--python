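"""Synthetic qPCR and RNA-Seq data with known ground truth.

The generator emulates a hatching time-course in potato cyst nematodes:
eight developmental conditions (dry cyst, hydrated cyst, five durations of
exposure to potato root diffusate, and hatched J2 larvae), three qPCR
replicates and two RNA-Seq replicates per condition.  Genes play roles:

* ``stable`` — constant expected Cq in every condition (true references);
* ``variable`` — small fixed per-condition shifts (ordinary genes);
* ``drift`` — a monotone trend across the condition order plus inflated
  replicate noise (the unstable-actin failure mode);
* ``noisy`` — no systematic shift but large replicate noise;
* ``pulse`` — strong overexpression in one or a few conditions (hatching
  genes used as validation targets).

Generative model on the Cq scale::

    Cq(g, s) = mu_g - delta_g(condition(s)) + L_s + eps,
    L_s ~ N(0, sigma_load),  eps ~ N(0, sqrt(sigma_tech^2 + extra_sd_g^2))

where ``delta_g`` is the role-defined log2 expression effect (positive =
overexpressed = lower Cq) and ``L_s`` a per-sample loading offset — the
sample-preparation variation that reference-gene normalization exists to
remove.  RNA-Seq counts are negative binomial around
``libsize_s * q_g / sum_g q_g`` with ``q_g = mean_expression_g *
2^delta_g(condition)``; dropout genes are forced to zero counts in their
designated conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import CountMatrix, CqTable, IntegrityError

__all__ = [
    "GeneSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_cq",
    "simulate_counts",
    "default_hatching_scenario",
    "screen_scenario",
    "HATCHING_CONDITIONS",
]

HATCHING_CONDITIONS = (
    "dry_cyst",
    "hydrated_cyst",
    "PRD_1h",
    "PRD_8h",
    "PRD_24h",
    "PRD_48h",
    "PRD_7d",
    "J2",
)


@dataclass(frozen=True)
class GeneSpec:
    """One gene of the simulated roster.

    ``condition_effects`` maps condition -> log2 expression effect delta
    (cycles; positive lowers Cq).  ``extra_sd`` adds gene-specific replicate
    noise in quadrature with the global technical SD.  ``mean_expression``
    is the linear-scale baseline abundance used for RNA-Seq counts.
    ``dropout_conditions`` force zero counts (RNA-Seq only).
    """

    name: str
    role: str = "stable"
    baseline_cq: float = 22.0
    condition_effects: dict[str, float] = field(default_factory=dict)
    extra_sd: float = 0.0
    mean_expression: float = 500.0
    dropout_conditions: tuple[str, ...] = ()

    def delta(self, condition: str) -> float:
        return float(self.condition_effects.get(condition, 0.0))


def drift_effects(
    conditions: tuple[str, ...], amplitude: float
) -> dict[str, float]:
    """Linear trend from 0 to ``amplitude`` log2 units across the conditions."""
    n = len(conditions)
    return {c: amplitude * i / (n - 1) for i, c in enumerate(conditions)}


@dataclass(frozen=True)
class SimulationConfig:
    """Design of one synthetic experiment."""

    genes: tuple[GeneSpec, ...]
    conditions: tuple[str, ...] = HATCHING_CONDITIONS
    qpcr_replicates: int = 3
    rnaseq_replicates: int = 2
    sigma_tech: float = 0.15  # replicate-to-replicate technical SD, cycles
    sigma_load: float = 0.3  # per-sample loading-offset SD, cycles
    nb_dispersion: float = 0.05  # NB dispersion (1/size); 0 = Poisson
    libsize_range: tuple[float, float] = (8e5, 1.2e6)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genes:
            raise IntegrityError("gene roster is empty")
        if self.sigma_tech < 0 or self.sigma_load < 0 or self.nb_dispersion < 0:
            raise IntegrityError("noise parameters must be >= 0")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise IntegrityError("duplicate gene names in roster")
        for g in self.genes:
            for c in g.condition_effects:
                if c not in self.conditions:
                    raise IntegrityError(
                        f"gene {g.name!r} has an effect for unknown condition {c!r}"
                    )

    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)

    def genes_with_role(self, role: str) -> list[str]:
        return [g.name for g in self.genes if g.role == role]


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually planted.

    ``expected`` is genes x conditions with the noise-free expected Cq
    (qPCR) or log2 relative expression effect (shared by both assays);
    ``loading_offsets`` maps sample -> the additive Cq offset it received.
    """

    roles: pd.Series
    expected_cq: pd.DataFrame
    effects: pd.DataFrame
    loading_offsets: pd.Series


def _sample_frame(
    conditions: tuple[str, ...], replicates: int
) -> pd.DataFrame:
    rows = [
        {"sample": f"{c}_{r}", "condition": c, "replicate": r}
        for c in conditions
        for r in range(1, replicates + 1)
    ]
    return pd.DataFrame(rows).set_index("sample")


def simulate_cq(cfg: SimulationConfig) -> tuple[CqTable, GroundTruth]:
    """Draw one replicate-level Cq table under the generative model."""
    rng = np.random.default_rng(cfg.seed)
    meta = _sample_frame(cfg.conditions, cfg.qpcr_replicates)
    samples = list(meta.index)
    offsets = pd.Series(
        rng.normal(0.0, cfg.sigma_load, size=len(samples)), index=samples
    )
    effects = pd.DataFrame(
        {c: [g.delta(c) for g in cfg.genes] for c in cfg.conditions},
        index=cfg.gene_names,
    )
    expected = pd.DataFrame(
        {
            c: [g.baseline_cq - g.delta(c) for g in cfg.genes]
            for c in cfg.conditions
        },
        index=cfg.gene_names,
    )
    values = pd.DataFrame(index=cfg.gene_names, columns=samples, dtype=float)
    for g in cfg.genes:
        sd = float(np.hypot(cfg.sigma_tech, g.extra_sd))
        noise = rng.normal(0.0, sd, size=len(samples)) if sd > 0 else 0.0
        base = np.array(
            [expected.loc[g.name, meta.loc[s, "condition"]] for s in samples]
        )
        values.loc[g.name] = base + offsets.to_numpy() + noise
    table = CqTable(values, meta)
    truth = GroundTruth(
        roles=pd.Series({g.name: g.role for g in cfg.genes}),
        expected_cq=expected,
        effects=effects,
        loading_offsets=offsets,
    )
    return table, truth


def simulate_counts(cfg: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw one RNA-Seq count matrix under the generative model."""
    rng = np.random.default_rng(cfg.seed + 1)  # decoupled from the qPCR draw
    meta = _sample_frame(cfg.conditions, cfg.rnaseq_replicates)
    samples = list(meta.index)
    lo, hi = cfg.libsize_range
    libsizes = rng.uniform(lo, hi, size=len(samples))
    effects = pd.DataFrame(
        {c: [g.delta(c) for g in cfg.genes] for c in cfg.conditions},
        index=cfg.gene_names,
    )
    q = pd.DataFrame(
        {
            c: [
                0.0
                if c in g.dropout_conditions
                else g.mean_expression * 2.0 ** g.delta(c)
                for g in cfg.genes
            ]
            for c in cfg.conditions
        },
        index=cfg.gene_names,
    )
    counts = pd.DataFrame(index=cfg.gene_names, columns=samples, dtype=np.int64)
    for i, s in enumerate(samples):
        cond = meta.loc[s, "condition"]
        qc = q[cond].to_numpy(dtype=float)
        total = qc.sum()
        mean = libsizes[i] * qc / total
        if cfg.nb_dispersion > 0:
            size = 1.0 / cfg.nb_dispersion
            p = size / (size + mean)
            drawn = np.where(mean > 0, rng.negative_binomial(size, np.clip(p, 1e-12, 1.0)), 0)
        else:
            drawn = rng.poisson(mean)
        counts[s] = drawn.astype(np.int64)
    matrix = CountMatrix(counts, meta)
    truth = GroundTruth(
        roles=pd.Series({g.name: g.role for g in cfg.genes}),
        expected_cq=pd.DataFrame(
            {
                c: [g.baseline_cq - g.delta(c) for g in cfg.genes]
                for c in cfg.conditions
            },
            index=cfg.gene_names,
        ),
        effects=effects,
        loading_offsets=pd.Series(libsizes, index=samples),
    )
    return matrix, truth


# fixed per-condition shifts for the mildly variable genes; distinct
# patterns with spreads of roughly 0.35-0.5 log2 units
_VARIABLE_EFFECTS = {
    "mce1": (0.0, 0.3, -0.3, 0.2, -0.2, 0.3, 0.0, -0.3),
    "ArgRS": (0.2, -0.2, 0.3, -0.3, 0.2, 0.0, -0.3, 0.3),
    "AMA-1": (-0.25, 0.25, 0.0, -0.25, 0.3, -0.2, 0.25, 0.0),
    "MDH-1": (0.3, 0.0, -0.3, 0.3, 0.0, -0.25, 0.25, -0.2),
    "CSQ-1": (-0.3, 0.3, 0.2, 0.0, -0.35, 0.3, -0.2, 0.2),
    "Y45F10D.4": (0.25, -0.3, 0.3, -0.2, 0.2, -0.3, 0.3, -0.25),
}


def default_hatching_scenario(seed: int = 0) -> SimulationConfig:
    """The bundled hatching time-course scenario.

    Fourteen genes: three planted stable references (aaRS, PMP-3, GR), six
    mildly variable candidates, one strongly drifting unstable gene
    (Act-1, 2.0-cycle trend plus 1.2-cycle replicate noise), one
    high-variance gene (EIF-3), and three pulse-like hatching targets —
    NEP-1 (10-fold at 8 h of root-diffusate exposure), cht-2 (6- and
    7-fold at 24 h / 48 h; zero counts in dry cysts on the RNA-Seq side)
    and eng (4-fold at 48 h).
    """
    conds = HATCHING_CONDITIONS
    genes = [
        GeneSpec("aaRS", "stable", 20.5, mean_expression=800.0),
        GeneSpec("PMP-3", "stable", 22.0, mean_expression=500.0),
        GeneSpec("GR", "stable", 21.0, mean_expression=650.0),
    ]
    base_cq = {"mce1": 23.0, "ArgRS": 21.5, "AMA-1": 24.0, "MDH-1": 22.5,
               "CSQ-1": 25.0, "Y45F10D.4": 24.5}
    base_expr = {"mce1": 300.0, "ArgRS": 700.0, "AMA-1": 200.0, "MDH-1": 400.0,
                 "CSQ-1": 150.0, "Y45F10D.4": 180.0}
    for name, shifts in _VARIABLE_EFFECTS.items():
        genes.append(
            GeneSpec(
                name,
                "variable",
                base_cq[name],
                condition_effects=dict(zip(conds, shifts)),
                mean_expression=base_expr[name],
            )
        )
    genes.append(
        GeneSpec(
            "Act-1",
            "drift",
            19.0,
            condition_effects=drift_effects(conds, 2.0),
            extra_sd=1.2,
            mean_expression=2000.0,
        )
    )
    genes.append(
        GeneSpec("EIF-3", "noisy", 20.0, extra_sd=1.5, mean_expression=1500.0)
    )
    genes.append(
        GeneSpec(
            "NEP-1",
            "pulse",
            28.0,
            condition_effects={"PRD_8h": float(np.log2(10.0))},
            mean_expression=50.0,
        )
    )
    genes.append(
        GeneSpec(
            "cht-2",
            "pulse",
            27.0,
            condition_effects={
                "PRD_24h": float(np.log2(6.0)),
                "PRD_48h": float(np.log2(7.0)),
            },
            mean_expression=60.0,
            dropout_conditions=("dry_cyst",),
        )
    )
    genes.append(
        GeneSpec(
            "eng",
            "pulse",
            26.5,
            condition_effects={"PRD_48h": float(np.log2(4.0))},
            mean_expression=80.0,
        )
    )
    return SimulationConfig(genes=tuple(genes), seed=seed)


def screen_scenario(
    n_background: int = 500,
    n_stable: int = 4,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> SimulationConfig:
    """A larger RNA-Seq roster for exercising the candidate screen.

    ``n_stable`` constant-mean genes are planted among ``n_background``
    condition-responsive genes (per-condition log2 shifts drawn once from
    N(0, 1)), plus one dropout gene with zero counts in one condition.
    ``noise_sd`` is the target replicate-level noise in log2 units; it is
    mapped onto the negative-binomial dispersion (and also used as the Cq
    technical SD if the qPCR side of the config is simulated).
    """
    rng = np.random.default_rng(seed)
    conds = HATCHING_CONDITIONS
    genes = [
        GeneSpec(f"STABLE_{i+1}", "stable", 21.0, mean_expression=500.0)
        for i in range(n_stable)
    ]
    for i in range(n_background):
        shifts = rng.normal(0.0, 1.0, size=len(conds))
        genes.append(
            GeneSpec(
                f"BG_{i+1:04d}",
                "variable",
                22.0,
                condition_effects=dict(zip(conds, shifts)),
                mean_expression=float(rng.uniform(50.0, 2000.0)),
            )
        )
    genes.append(
        GeneSpec(
            "DROPOUT_1",
            "dropout",
            25.0,
            mean_expression=100.0,
            dropout_conditions=("PRD_24h",),
        )
    )
    return SimulationConfig(
        genes=tuple(genes),
        sigma_tech=noise_sd,
        sigma_load=0.0,
        # NB dispersion chosen so the count noise is ~noise_sd log2 units
        # on top of the Poisson floor: Var(log x) ~ CV^2 = 1/mean + phi
        nb_dispersion=float((noise_sd * np.log(2.0)) ** 2),
        seed=seed,
    )
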