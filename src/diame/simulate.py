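"""Synthetic two-proteome spike-in report tables and single-cell matrices.

The two-proteome generator emulates the benchmark design in which a base human
proteome is mixed with a foreign (entrapment) proteome at a weight fraction rho
that replaces part of the human material, at total peptide inputs between 1 and
100 ng. Low-input analyte runs are co-analyzed with higher-input
matching-enhancer (ME) runs: features undetected in the first pass of an
analyte but present in an ME can be recovered by matching (true transfers),
while entrapment features that are absent from a non-spiked analyte can leak in
(false transfers). The generator works at the report-table level — peptide
intensities, detection, matching, q-values — not at the raw-signal level, and
keeps complete per-record ground truth so estimator-recovery properties can be
tested exactly.

Intensity model per feature (one precursor of one protein) and run::

    log2 I = unit + log2(amount_ng) + loading + log2(w_species / S_species)
             + base + noise,      noise ~ N(0, noise_sd_log2)

where ``w_species`` is ``1 - rho`` (human) or ``rho`` (entrapment) and
``S_species`` normalizes each proteome's features to unit total mass, so a
sample's total linear intensity is proportional to amount x loading regardless
of composition — the property the spike design relies on for normalization.
First-pass detection is Bernoulli with a logistic probability in realized log2
intensity, making low-intensity features preferentially missing.

``false_transfer_prob`` is the expected fraction of matching-gained
identifications that are false: per analyte run the per-candidate leak
probability is scaled as ``f/(1-f) * T/C`` (T realized true transfers, C leak
candidates) so that the pooled false-transfer rate converges to the configured
value — the generator's headline recovery property.

q-values are drawn marginally: Beta(1, 200) for genuine identifications and
Uniform(0, 0.05) for false transfers, so false identifications partially
survive default 1% filtering instead of being trivially separable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .report_io import ReportTable

__all__ = [
    "SimCondition",
    "SimulationConfig",
    "GroundTruth",
    "SingleCellConfig",
    "SingleCellTruth",
    "simulate_two_proteome",
    "simulate_single_cells",
    "truth_rates",
    "study_design",
    "spiked_dilution_design",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimCondition:
    """One sample condition: role, spike fraction (w/w) and input amount (ng)."""

    name: str
    role: str  # analyte | me | blank
    spike_fraction: float
    input_amount_ng: float
    n_replicates: int

    def __post_init__(self) -> None:
        if self.role not in ("analyte", "me", "blank"):
            raise ValueError(f"unknown role {self.role!r}")
        if not 0.0 <= self.spike_fraction < 1.0:
            raise ValueError("spike fraction must lie in [0, 1)")
        if self.input_amount_ng <= 0 or self.n_replicates < 1:
            raise ValueError("input amount must be positive and n_replicates >= 1")


@dataclass
class SimulationConfig:
    """Two-proteome spike-in simulation parameters. ``seed`` is mandatory."""

    seed: int
    conditions: list[SimCondition]
    n_human_proteins: int = 1500
    n_entrapment_proteins: int = 400
    peptides_per_protein_mean: float = 8.0
    abundance_loc_log2: float = 20.0
    abundance_scale_log2: float = 2.5
    peptide_scale_log2: float = 1.5
    loading_jitter_log2: float = float(np.log2(1.3))  # uniform half-width, +/-30%
    intensity_unit_log2: float = 50.0
    detection_midpoint_log2: float = 34.5
    detection_slope_log2: float = 2.0
    true_transfer_prob: float = 0.8
    false_transfer_prob: float = 0.002
    noise_sd_log2: float = 0.15
    qvalue_true_beta: tuple[float, float] = (1.0, 200.0)
    qvalue_false_max: float = 0.05
    pgq_global_beta: tuple[float, float] = (1.0, 500.0)
    pgq_run_beta: tuple[float, float] = (1.0, 300.0)
    shared_fraction: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.true_transfer_prob, self.false_transfer_prob, self.shared_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.false_transfer_prob >= 1.0:
            raise ValueError("false_transfer_prob must be < 1")
        spiked = any(c.spike_fraction > 0 for c in self.conditions)
        if spiked and self.n_entrapment_proteins == 0:
            raise ValueError("spiked conditions require entrapment proteins")
        if not self.conditions:
            raise ValueError("at least one condition required")


@dataclass
class GroundTruth:
    """Generator bookkeeping for estimator-recovery tests."""

    labels: pd.DataFrame  # run_id, precursor_id, label in {first_pass, true_transfer, false_transfer}
    loading_log2: pd.Series  # run_id -> loading factor (log2)
    protein_abundance: pd.DataFrame  # protein x condition true linear abundance
    rates: dict[str, float]


def study_design(
    n_analyte: int = 7,
    analyte_amount_ng: float = 1.0,
    me_fold: float = 10.0,
    rho_me: float = 0.10,
    n_me: int = 3,
) -> list[SimCondition]:
    """Non-spiked low-input analytes co-analyzed with spiked higher-input MEs."""
    return [
        SimCondition("analyte", "analyte", 0.0, analyte_amount_ng, n_analyte),
        SimCondition(f"me_{int(rho_me * 100)}pct", "me", rho_me, analyte_amount_ng * me_fold, n_me),
    ]


def spiked_dilution_design(
    rhos: tuple[float, ...] = (0.05, 0.10, 0.20),
    n_replicates: int = 3,
    amount_ng: float = 1.0,
    me_fold: float = 10.0,
    n_me: int = 1,
) -> list[SimCondition]:
    """Spiked analyte triplicates per rho plus matched higher-input ME runs."""
    conditions = [
        SimCondition(f"rho_{int(r * 100):02d}", "analyte", r, amount_ng, n_replicates) for r in rhos
    ]
    conditions += [
        SimCondition(f"me_rho_{int(r * 100):02d}", "me", r, amount_ng * me_fold, n_me) for r in rhos
    ]
    return conditions


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_two_proteome(cfg: SimulationConfig) -> tuple[ReportTable, pd.DataFrame, GroundTruth]:
    """Simulate a report table, sample annotations and ground truth.

    Identical seeds give byte-identical output.
    """
    rng = np.random.default_rng(cfg.seed)

    # --- proteome: proteins, peptides-per-protein, per-feature base abundance
    n_prot = cfg.n_human_proteins + cfg.n_entrapment_proteins
    prot_ids = np.array(
        [f"HUMAN_P{i:05d}" for i in range(cfg.n_human_proteins)]
        + [f"ECOLI_P{i:05d}" for i in range(cfg.n_entrapment_proteins)]
    )
    prot_species = np.array(["human"] * cfg.n_human_proteins + ["entrapment"] * cfg.n_entrapment_proteins)
    n_pep = rng.geometric(1.0 / cfg.peptides_per_protein_mean, size=n_prot).clip(1, 60)
    prot_base = rng.normal(cfg.abundance_loc_log2, cfg.abundance_scale_log2, size=n_prot)

    feat_prot = np.repeat(np.arange(n_prot), n_pep)
    n_feat = feat_prot.size
    feat_base = prot_base[feat_prot] + rng.normal(0.0, cfg.peptide_scale_log2, size=n_feat)
    feat_species = prot_species[feat_prot]
    feat_group = prot_ids[feat_prot].astype(object)
    feat_precursor = np.array([f"PEP{i:06d}/2" for i in range(n_feat)], dtype=object)

    if cfg.shared_fraction > 0:
        human_feats = np.flatnonzero(feat_species == "human")
        n_shared = int(round(cfg.shared_fraction * human_feats.size))
        chosen = rng.choice(human_feats, size=n_shared, replace=False)
        partners = rng.integers(cfg.n_human_proteins, n_prot, size=n_shared)
        for f, p in zip(chosen, partners):
            feat_group[f] = f"{feat_group[f]};{prot_ids[p]}"
        feat_species = feat_species.copy()
        feat_species[chosen] = "shared"

    is_human = feat_species != "entrapment"  # shared features ride on the human proteome mass
    mass_h = np.exp2(feat_base[is_human]).sum()
    mass_e = np.exp2(feat_base[~is_human]).sum() if (~is_human).any() else 1.0
    log_s = np.where(is_human, np.log2(mass_h), np.log2(mass_e))

    # --- runs
    runs: list[tuple[str, SimCondition, int]] = []
    for cond in cfg.conditions:
        for rep in range(1, cond.n_replicates + 1):
            runs.append((f"{cond.name}_r{rep}", cond, rep))
    loading = pd.Series(
        rng.uniform(-cfg.loading_jitter_log2, cfg.loading_jitter_log2, size=len(runs)),
        index=[r[0] for r in runs],
        name="loading_log2",
    )

    # --- per-run true intensities and first-pass detection
    per_run: dict[str, dict[str, np.ndarray]] = {}
    for run_id, cond, _rep in runs:
        w = np.where(is_human, 1.0 - cond.spike_fraction, cond.spike_fraction)
        present = w > 0
        x_true = np.full(n_feat, -np.inf)
        x_true[present] = (
            cfg.intensity_unit_log2
            + np.log2(cond.input_amount_ng)
            + loading[run_id]
            + np.log2(w[present])
            - log_s[present]
            + feat_base[present]
        )
        noise = rng.normal(0.0, cfg.noise_sd_log2, size=n_feat)
        x_obs = x_true + noise
        p_det = np.where(
            present,
            _sigmoid((x_obs - cfg.detection_midpoint_log2) / cfg.detection_slope_log2),
            0.0,
        )
        detected = rng.random(n_feat) < p_det
        per_run[run_id] = {"present": present, "x_obs": x_obs, "detected": detected}

    me_runs = [r for r, c, _ in runs if c.role == "me"]
    analyte_runs = [r for r, c, _ in runs if c.role == "analyte"]

    # --- matching: true and false transfers into analyte runs
    records: list[pd.DataFrame] = []
    label_frames: list[pd.DataFrame] = []
    for run_id, cond, _rep in runs:
        state = per_run[run_id]
        rows = {"first_pass": np.flatnonzero(state["detected"])}

        if cond.role == "analyte":
            donors = me_runs if me_runs else [r for r in analyte_runs if r != run_id]
            if donors:
                donor_det = np.zeros(n_feat, dtype=bool)
                for d in donors:
                    donor_det |= per_run[d]["detected"]
                eligible_true = state["present"] & ~state["detected"] & donor_det
                take_true = eligible_true & (rng.random(n_feat) < cfg.true_transfer_prob)
                rows["true_transfer"] = np.flatnonzero(take_true)

                candidates = ~state["present"] & donor_det
                n_cand = int(candidates.sum())
                n_true = int(take_true.sum())
                f = cfg.false_transfer_prob
                if f > 0 and n_cand > 0 and n_true > 0:
                    leak_p = min(f / (1.0 - f) * n_true / n_cand, 1.0)
                    if leak_p == 1.0:
                        log.warning("run %s: leak probability clipped to 1", run_id)
                    take_false = candidates & (rng.random(n_feat) < leak_p)
                    rows["false_transfer"] = np.flatnonzero(take_false)

        frames = []
        for label, idx in rows.items():
            if idx.size == 0:
                continue
            if label == "false_transfer":
                # no true presence in this run: report the intensity the feature
                # would have at the acceptor's amount and loading if spiked like a donor
                donor_rho = max(c.spike_fraction for _r, c, _ in runs if c.role == "me") if me_runs else 0.1
                x = (
                    cfg.intensity_unit_log2
                    + np.log2(cond.input_amount_ng)
                    + loading[run_id]
                    + np.log2(donor_rho)
                    - log_s[idx]
                    + feat_base[idx]
                    + rng.normal(0.0, cfg.noise_sd_log2, size=idx.size)
                )
            else:
                # matched records carry the realized (noisy) intensity; for true
                # transfers this is conditioned on first-pass non-detection,
                # mirroring the slightly low-biased quantities of recovered IDs
                x = per_run[run_id]["x_obs"][idx]
            a_true, b_true = cfg.qvalue_true_beta
            if label == "false_transfer":
                q_run = rng.uniform(0.0, cfg.qvalue_false_max, size=idx.size)
                q_global = rng.uniform(0.0, cfg.qvalue_false_max, size=idx.size)
            else:
                q_run = rng.beta(a_true, b_true, size=idx.size)
                q_global = rng.beta(a_true, b_true, size=idx.size)
            frames.append(
                pd.DataFrame(
                    {
                        "run_id": run_id,
                        "protein_group": feat_group[idx],
                        "precursor_id": feat_precursor[idx],
                        "intensity": np.exp2(x),
                        "q_run": q_run,
                        "q_global": q_global,
                        "pgq_run": np.nan,
                        "pgq_global": np.nan,
                        "species": feat_species[idx],
                        "provenance": "first_pass" if label == "first_pass" else "matched",
                        "_label": label,
                    }
                )
            )
        if frames:
            run_df = pd.concat(frames, ignore_index=True)
            records.append(run_df.drop(columns="_label"))
            label_frames.append(run_df[["run_id", "precursor_id", "_label"]].rename(columns={"_label": "label"}))

    report_df = pd.concat(records, ignore_index=True)

    # protein-group q-values: one global draw per group, one run-level draw per (group, run)
    groups = report_df["protein_group"].unique()
    a_g, b_g = cfg.pgq_global_beta
    pgq_global = pd.Series(rng.beta(a_g, b_g, size=groups.size), index=groups)
    report_df["pgq_global"] = report_df["protein_group"].map(pgq_global)
    a_r, b_r = cfg.pgq_run_beta
    pairs = report_df[["protein_group", "run_id"]].drop_duplicates()
    pgq_run = pd.Series(
        rng.beta(a_r, b_r, size=len(pairs)),
        index=pd.MultiIndex.from_frame(pairs),
    )
    report_df["pgq_run"] = pd.MultiIndex.from_frame(report_df[["protein_group", "run_id"]]).map(pgq_run)

    annotations = pd.DataFrame(
        {
            "run_id": [r for r, _c, _rep in runs],
            "role": [c.role for _r, c, _rep in runs],
            "condition": [c.name for _r, c, _rep in runs],
            "replicate": [rep for _r, _c, rep in runs],
        }
    )

    abundance = pd.DataFrame(
        {
            cond.name: np.where(
                prot_species == "human", 1.0 - cond.spike_fraction, cond.spike_fraction
            )
            * cond.input_amount_ng
            * np.exp2(prot_base)
            / np.where(prot_species == "human", mass_h, mass_e)
            for cond in cfg.conditions
        },
        index=prot_ids,
    )

    truth = GroundTruth(
        labels=pd.concat(label_frames, ignore_index=True),
        loading_log2=loading,
        protein_abundance=abundance,
        rates={
            "true_transfer_prob": cfg.true_transfer_prob,
            "false_transfer_prob": cfg.false_transfer_prob,
        },
    )
    return ReportTable(report_df), annotations, truth


def truth_rates(gt: GroundTruth) -> pd.DataFrame:
    """Realized per-run transfer counts and false rate among matched records."""
    counts = (
        gt.labels.groupby(["run_id", "label"]).size().unstack(fill_value=0)
    )
    for col in ("first_pass", "true_transfer", "false_transfer"):
        if col not in counts:
            counts[col] = 0
    counts = counts[["first_pass", "true_transfer", "false_transfer"]]
    matched = counts["true_transfer"] + counts["false_transfer"]
    counts["false_rate"] = np.where(matched > 0, counts["false_transfer"] / matched, np.nan)
    counts.index.name = "run_id"
    return counts


# --------------------------------------------------------------------------
# single-cell generator


@dataclass
class SingleCellConfig:
    """Planted-structure single-cell protein matrix parameters.

    Two protein modules load with opposite sign on a latent cell-state score
    (strong internal correlation, mutual anti-correlation); an independent
    responder set shifts by ``effect_log2`` in treated cells. Detection is off
    (complete matrix) unless ``detection_midpoint_log2`` is set.
    """

    seed: int
    n_proteins: int = 200
    n_control: int = 30
    n_treated: int = 30
    module_sizes: tuple[int, int] = (30, 30)
    module_loading_log2: float = 1.0
    responder_count: int = 25
    effect_log2: float = 1.0
    noise_sd_log2: float = 0.5
    baseline_loc_log2: float = 14.0
    baseline_scale_log2: float = 2.0
    detection_midpoint_log2: float | None = None
    detection_slope_log2: float = 1.5

    def __post_init__(self) -> None:
        if sum(self.module_sizes) + self.responder_count > self.n_proteins:
            raise ValueError("module sizes plus responders exceed protein count")
        if self.n_control < 1 or self.n_treated < 1:
            raise ValueError("need at least one cell per group")


@dataclass
class SingleCellTruth:
    modules: pd.Series  # protein -> 0 (none), 1, 2
    responders: list[str]
    latent: pd.Series  # cell -> latent state score
    treatment: pd.Series  # cell -> control | treated


def simulate_single_cells(cfg: SingleCellConfig) -> tuple[pd.DataFrame, SingleCellTruth]:
    """Simulate a protein x cell log2 matrix with planted co-variation modules."""
    rng = np.random.default_rng(cfg.seed)
    proteins = [f"PROT_{i:05d}" for i in range(cfg.n_proteins)]
    cells = [f"CELL_C{i:04d}" for i in range(cfg.n_control)] + [
        f"CELL_T{i:04d}" for i in range(cfg.n_treated)
    ]
    treated = np.array([False] * cfg.n_control + [True] * cfg.n_treated)

    m1, m2 = cfg.module_sizes
    modules = np.zeros(cfg.n_proteins, dtype=int)
    modules[:m1] = 1
    modules[m1 : m1 + m2] = 2
    responders = list(range(m1 + m2, m1 + m2 + cfg.responder_count))

    baseline = rng.normal(cfg.baseline_loc_log2, cfg.baseline_scale_log2, size=cfg.n_proteins)
    latent = rng.normal(0.0, 1.0, size=len(cells))
    loadings = np.where(modules == 1, cfg.module_loading_log2, 0.0) - np.where(
        modules == 2, cfg.module_loading_log2, 0.0
    )

    x = baseline[:, None] + loadings[:, None] * latent[None, :]
    x[responders, :] += cfg.effect_log2 * treated[None, :]
    x = x + rng.normal(0.0, cfg.noise_sd_log2, size=x.shape)

    if cfg.detection_midpoint_log2 is not None:
        p_det = _sigmoid((x - cfg.detection_midpoint_log2) / cfg.detection_slope_log2)
        x = np.where(rng.random(x.shape) < p_det, x, np.nan)

    matrix = pd.DataFrame(x, index=proteins, columns=cells)
    matrix.index.name = "protein_group"
    matrix.columns.name = "cell"
    truth = SingleCellTruth(
        modules=pd.Series(modules, index=proteins, name="module"),
        responders=[proteins[i] for i in responders],
        latent=pd.Series(latent, index=cells, name="latent"),
        treatment=pd.Series(np.where(treated, "treated", "control"), index=cells, name="treatment"),
    )
    return matrix, truth
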