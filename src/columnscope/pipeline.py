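"""End-to-end orchestration: simulate, map, and analyze a synthetic study.

`run_pipeline` chains the stages the analyses need — synthetic cortex and
behavior, first-level GLM contrast maps per depth, radial-vs-tangential
correlation tables, gray-vs-above-surface vessel controls, overlap curves
with shuffle nulls, session consistency, patch counts, distance tuning, and
rate-model response profiles — with per-stage seeds derived from one master
seed, and `write_report` renders the bundle as a Markdown report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import columnarity, geometry, glm, interdigitation, ratemodel, reported
from . import synthetic, tuning

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration of the demo pipeline."""

    seed: int = 0
    nx: int = 128
    ny: int = 128
    dx_mm: float = 0.5
    mean_thickness_mm: float = synthetic.DEFAULT_THICKNESS_MM
    n_depth_planes: int = 12
    n_subjects: int = 7
    # column families: columns per cm^2; the approach/near poles are more
    # numerous than their counterparts, as observed
    density_per_cm2: dict = field(default_factory=lambda: {
        "PA": 0.8, "PW": 0.5, "DN": 0.8, "DF": 0.6})
    radius_range_mm: tuple = (1.2, 2.0)
    # BOLD generator (signal units: % of a 100-unit baseline)
    amp_preferred: float = 2.0
    amp_nonpreferred: float = 0.5
    amp_nonselective: float = 1.0
    vessel_gain: float = 2.0
    noise_sd: float = 1.0
    # analysis
    lateral_offset_mm: float = 1.9
    deep_frac: float = 0.8
    superficial_frac: float = 0.1
    above_mm: tuple = (-1.2, -1.9, -2.4)
    overlap_thresholds: tuple = (1.3, 2.0, 3.0, 4.0, 5.0)
    n_shuffles: int = 1000
    patch_min_size: int = 5
    # behavior / tuning
    sdp_mean_cm: float = reported.SDP_MEAN_CM
    sdp_between_sd_cm: float = reported.SDP_SD_CM
    sdp_within_sd_cm: float = 6.0
    sdp_n_trials: int = 5
    ps_boundary_range_cm: tuple = (40.0, 90.0)
    events_per_distance: int = 6
    # rate model
    i_grid: tuple = (0.0, 100.0, 201)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        for key in ("radius_range_mm", "above_mm", "overlap_thresholds",
                    "ps_boundary_range_cm", "i_grid"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def _stage(name: str, seed: int):
    logger.info("stage=%s seed=%d start", name, seed)
    return time.perf_counter()


def _stage_done(name: str, t0: float) -> None:
    logger.info("stage=%s wall=%.2fs done", name, time.perf_counter() - t0)


def _exp1_amplitudes(cfg: RunConfig) -> dict[str, dict[str, float]]:
    return {
        "approach": {"PA": cfg.amp_preferred, "PW": cfg.amp_nonpreferred,
                     "DN": cfg.amp_nonselective, "DF": cfg.amp_nonselective},
        "withdrawal": {"PA": cfg.amp_nonpreferred, "PW": cfg.amp_preferred,
                       "DN": cfg.amp_nonselective, "DF": cfg.amp_nonselective},
    }


def _exp3_amplitudes(cfg: RunConfig) -> dict[str, dict[str, float]]:
    return {
        "near": {"DN": cfg.amp_preferred, "DF": cfg.amp_nonpreferred,
                 "PA": cfg.amp_nonselective, "PW": cfg.amp_nonselective},
        "far": {"DN": cfg.amp_nonpreferred, "DF": cfg.amp_preferred,
                "PA": cfg.amp_nonselective, "PW": cfg.amp_nonselective},
    }


def _contrast_plane(
    labels: synthetic.ColumnLabelMap,
    cfg: RunConfig,
    experiment: str,
    seed: int,
    vessel_pattern: np.ndarray | None = None,
) -> glm.ContrastMap:
    """Simulate one run at one depth plane and map its two-pole contrast.

    Within-gray planes carry the label-driven amplitudes; above-pia planes
    (``vessel_pattern`` given) carry only vessel-patterned signal, spatially
    unrelated to the columns.
    """
    rng = np.random.default_rng(seed)
    if experiment == "exp1":
        events, n_tp = synthetic.block_design(seed=int(rng.integers(2**31)))
        amps = _exp1_amplitudes(cfg)
        conds = ("approach", "withdrawal")
    else:
        events, n_tp = synthetic.disparity_block_design(
            seed=int(rng.integers(2**31)))
        amps = _exp3_amplitudes(cfg)
        conds = ("near", "far")
    if vessel_pattern is not None:
        amps = {conds[0]: {"pattern": 0.5 * cfg.vessel_gain},
                conds[1]: {"pattern": -0.5 * cfg.vessel_gain}}
    run = synthetic.simulate_bold_run(
        labels, events, n_tp, amps, noise_sd=cfg.noise_sd,
        amplitude_pattern=vessel_pattern, seed=int(rng.integers(2**31)))
    design = glm.build_design_matrix(run.events, run.n_timepoints, run.tr,
                                     motion=run.motion)
    fit = glm.fit_glm(run.series, design)
    return glm.contrast_map(fit, design.condition_contrast(*conds),
                            name=f"{conds[0]}-{conds[1]}")


def _simulate_subject(cfg: RunConfig, seed: int):
    """Sheet, labels, and vessel layer for one synthetic subject."""
    ss = np.random.SeedSequence(seed)
    s_sheet, s_cols, s_vessel = [int(c.generate_state(1)[0] % 2**31)
                                 for c in ss.spawn(3)]
    depth_axis = synthetic.default_depth_axis(
        max_below_mm=cfg.mean_thickness_mm,
        n_above=4, n_below=max(cfg.n_depth_planes - 4, 2))
    sheet = synthetic.make_sheet(cfg.nx, cfg.ny, cfg.dx_mm,
                                 cfg.mean_thickness_mm,
                                 depth_axis=depth_axis, seed=s_sheet)
    labels = synthetic.plant_columns(
        sheet, cfg.density_per_cm2, cfg.radius_range_mm, seed=s_cols)
    p_pattern = (labels.mask("PA").astype(float)
                 - labels.mask("PW").astype(float))
    vessel = synthetic.make_vessel_layer(
        sheet, decorrelate_from=p_pattern, seed=s_vessel)
    return sheet, labels, vessel


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the artifact bundle (a dict of tables).

    Each stage draws its seeds from a child of ``config.seed``; identical
    configs produce identical bundles.
    """
    cfg = config
    bundle: dict = {"config": cfg, "config_hash": cfg.config_hash()}
    master = np.random.SeedSequence(cfg.seed)
    seeds = [int(c.generate_state(1)[0] % 2**31) for c in master.spawn(8)]
    (s_geom, s_behav, s_subjects, s_overlap, s_session, s_tuning,
     s_rate, s_extra) = seeds

    # -- stimulus geometry worked examples ---------------------------------
    t0 = _stage("geometry", s_geom)
    geom = geometry.ViewingGeometry()
    rows = []
    for d in (39.0, 57.0, 114.0, 300.0):
        rows.append({"virtual_distance_cm": d, **geometry.project_face(geom, d)})
    bundle["geometry_examples"] = pd.DataFrame(rows)
    bundle["distance_grid_60cm"] = pd.DataFrame({
        "percent": geometry.PS_GRID_PERCENTAGES,
        "distance_cm": geometry.ps_distance_grid(60.0).distances,
    })
    _stage_done("geometry", t0)

    # -- behavior: stop-distance trials and summary ------------------------
    t0 = _stage("behavior", s_behav)
    rng = np.random.default_rng(s_behav)
    trials = []
    for s in range(cfg.n_subjects):
        subj_mean = float(rng.normal(cfg.sdp_mean_cm, cfg.sdp_between_sd_cm))
        subj_mean = max(subj_mean, 20.0)
        trials.append(synthetic.simulate_sdp_trials(
            subj_mean, cfg.sdp_within_sd_cm, cfg.sdp_n_trials,
            subject=f"s{s + 1}", seed=int(rng.integers(2**31))))
    summary = geometry.sdp_summary(trials)
    bundle["sdp_summary"] = summary
    bundle["sdp_per_subject"] = summary.per_subject
    _stage_done("behavior", t0)

    # -- columnarity & vessel control across synthetic subjects ------------
    t0 = _stage("columnarity", s_subjects)
    subj_rng = np.random.default_rng(s_subjects)
    axis_rows, vessel_rows = [], []
    first_subject = None
    for s in range(cfg.n_subjects):
        sheet, labels, vessel = _simulate_subject(
            cfg, int(subj_rng.integers(2**31)))
        if first_subject is None:
            first_subject = (sheet, labels, vessel)
        plane_maps: dict[tuple[str, float], np.ndarray] = {}
        for frac in (0.0, cfg.superficial_frac, cfg.deep_frac, 0.9):
            cmap = _contrast_plane(labels, cfg, "exp1",
                                   int(subj_rng.integers(2**31)))
            plane_maps[("frac", frac)] = cmap.signed_logp
        for mm in cfg.above_mm:
            cmap = _contrast_plane(labels, cfg, "exp1",
                                   int(subj_rng.integers(2**31)),
                                   vessel_pattern=vessel.pattern)
            plane_maps[("mm", mm)] = cmap.signed_logp
        stats_row = columnarity.axis_correlations(
            plane_maps[("frac", cfg.superficial_frac)],
            plane_maps[("frac", 0.9)],
            cfg.lateral_offset_mm, cfg.dx_mm)
        axis_rows.append(stats_row)
        vessel_rows.append(columnarity.vessel_control_correlations(
            plane_maps[("frac", cfg.deep_frac)],
            plane_maps[("frac", 0.0)],
            {mm: plane_maps[("mm", mm)] for mm in cfg.above_mm}))
    axis_table, axis_tests = columnarity.axis_correlation_table(axis_rows)
    vessel_table, vessel_tests = columnarity.vessel_control_table(vessel_rows)
    bundle["axis_table"] = axis_table
    bundle["axis_tests"] = axis_tests
    bundle["vessel_table"] = vessel_table
    bundle["vessel_tests"] = vessel_tests
    _stage_done("columnarity", t0)

    # -- interdigitation: cross-contrast overlap curves --------------------
    t0 = _stage("overlap", s_overlap)
    sheet, labels, vessel = first_subject
    rng = np.random.default_rng(s_overlap)
    p_map = _contrast_plane(labels, cfg, "exp1", int(rng.integers(2**31)))
    d_density = sum(cfg.density_per_cm2.get(k, 0.0) for k in ("DN", "DF"))
    if d_density > 0:
        d_map = _contrast_plane(labels, cfg, "exp3", int(rng.integers(2**31)))
        pairs = {
            "approach_vs_near": (p_map, d_map, ("positive", "positive")),
            "approach_vs_far": (p_map, d_map, ("positive", "negative")),
            "withdrawal_vs_near": (p_map, d_map, ("negative", "positive")),
            "withdrawal_vs_far": (p_map, d_map, ("negative", "negative")),
        }
        bundle["overlap_curves"] = {
            name: interdigitation.overlap_curve(
                m1, m2, cfg.overlap_thresholds, poles=poles,
                n_shuffles=cfg.n_shuffles, seed=int(rng.integers(2**31)))
            for name, (m1, m2, poles) in pairs.items()}
    else:
        logger.warning("D-family density is 0; disparity contrasts are "
                       "empty and overlap curves are skipped")
        bundle["overlap_curves"] = {}
    # patch counts per pole across thresholds
    patch_rows = []
    for thr in (2.0, 3.0, 4.0, 5.0):
        for pole, name in (("positive", "approach"), ("negative", "withdrawal")):
            mask = interdigitation.threshold_map(p_map, thr, pole=pole)
            patch_rows.append({
                "threshold": thr, "pole": name,
                "n_patches": interdigitation.count_patches(
                    mask, min_size=cfg.patch_min_size)})
    bundle["patch_counts"] = pd.DataFrame(patch_rows)
    _stage_done("overlap", t0)

    # -- session consistency ------------------------------------------------
    t0 = _stage("session_consistency", s_session)
    rng = np.random.default_rng(s_session)
    m_s1 = _contrast_plane(labels, cfg, "exp1", int(rng.integers(2**31)))
    m_s2 = _contrast_plane(labels, cfg, "exp1", int(rng.integers(2**31)))
    rows = []
    for pole, name in (("positive", "approach"), ("negative", "withdrawal")):
        b1 = interdigitation.threshold_map(m_s1, 1.3, pole=pole)
        b2 = interdigitation.threshold_map(m_s2, 1.3, pole=pole)
        res = interdigitation.shuffled_null(
            b1, b2, cfg.n_shuffles, seed=int(rng.integers(2**31)))
        rows.append({"pole": name, "aligned": res.aligned_overlap,
                     "null_mean": res.null_mean, "p_upper": res.p_upper})
    bundle["session_consistency"] = pd.DataFrame(rows)
    _stage_done("session_consistency", t0)

    # -- distance tuning -----------------------------------------------------
    t0 = _stage("tuning", s_tuning)
    rng = np.random.default_rng(s_tuning)
    ps = float(rng.uniform(*cfg.ps_boundary_range_cm))
    curves, classes = _tuning_for_subject(labels, cfg, ps,
                                          int(rng.integers(2**31)))
    bundle["tuning_curves"] = curves
    bundle["tuning_classes"] = classes
    _stage_done("tuning", t0)

    # -- rate model -----------------------------------------------------------
    t0 = _stage("rate_model", s_rate)
    lo, hi, n = cfg.i_grid
    grid = np.linspace(lo, hi, int(n))
    profiles, regimes = {}, {}
    for name in ("approach", "withdrawal"):
        prof = ratemodel.response_profile(ratemodel.preset(name), grid)
        profiles[name] = prof
        regimes[name] = ratemodel.classify_profile(prof)
    bundle["rate_profiles"] = profiles
    bundle["rate_regimes"] = regimes
    _stage_done("rate_model", t0)

    # -- recomputation of the published statistics ---------------------------
    bundle["reported_checks"] = recompute_reported_statistics()
    return bundle


def _tuning_for_subject(
    labels: synthetic.ColumnLabelMap,
    cfg: RunConfig,
    ps_boundary_cm: float,
    seed: int,
) -> tuple[dict[str, tuning.TuningCurve], dict[str, str]]:
    """Simulate the event-related experiment and recover tuning curves."""
    rng = np.random.default_rng(seed)
    pcts = geometry.PS_GRID_PERCENTAGES
    conditions = [f"{p:.0f}" for p in pcts]
    events, n_tp = synthetic.event_design(
        conditions, cfg.events_per_distance, seed=int(rng.integers(2**31)))
    amps = {}
    for cond, p in zip(conditions, pcts):
        amps[cond] = {"PA": float(tuning.approach_profile(p)),
                      "PW": float(tuning.withdrawal_profile(p)),
                      "DN": 0.0, "DF": 0.0}
    run = synthetic.simulate_bold_run(
        labels, events, n_tp, amps, noise_sd=cfg.noise_sd,
        seed=int(rng.integers(2**31)))
    betas = tuning.event_response_amplitudes(
        run, {"PA": labels.mask("PA"), "PW": labels.mask("PW")})
    betas["distance_pct"] = betas["condition"].astype(float)
    curves, classes = {}, {}
    for roi, ctype in (("PA", "approach"), ("PW", "withdrawal")):
        curve = tuning.build_tuning_curve(
            betas[betas["roi"] == roi], ps_boundary_cm, column_type=ctype)
        curves[ctype] = curve
        classes[ctype] = tuning.classify_tuning(curve)
    return curves, classes


def recompute_reported_statistics() -> pd.DataFrame:
    """Re-run the package's statistics on the published per-subject tables.

    Reproduces the printed paired-t statistics: the axis-correlation
    comparisons (Fisher z then paired t) and the gray-vs-above-surface
    control comparisons (paired t on raw r).
    """
    rows = []
    ax = reported.AXIS_CORRELATIONS
    for col, printed, label in (
            ("r_across_deep", reported.AXIS_T_WITHIN_VS_DEEP,
             "axis_within_vs_deep"),
            ("r_across_superficial", reported.AXIS_T_WITHIN_VS_SUPERFICIAL,
             "axis_within_vs_superficial")):
        t, df, p = columnarity.paired_t(
            columnarity.fisher_z(ax["r_within"]),
            columnarity.fisher_z(ax[col]))
        rows.append({"comparison": label, "t": t, "df": df, "p": p,
                     "printed_t": printed})
    vc = reported.VESSEL_CONTROL_CORRELATIONS
    for col, printed in (("B", reported.VESSEL_T_A_VS_B),
                         ("C", reported.VESSEL_T_A_VS_C),
                         ("D", reported.VESSEL_T_A_VS_D)):
        t, df, p = columnarity.paired_t(vc["A"], vc[col])
        rows.append({"comparison": f"vessel_A_vs_{col}", "t": t, "df": df,
                     "p": p, "printed_t": printed})
    return pd.DataFrame(rows)


def bundle_checksums(bundle: dict) -> dict[str, str]:
    """Stable SHA-256 digests of every table/array in a bundle."""
    out = {}
    for key, val in sorted(bundle.items()):
        if isinstance(val, pd.DataFrame):
            out[key] = hashlib.sha256(
                val.round(12).to_csv().encode()).hexdigest()[:16]
        elif isinstance(val, dict):
            for sub, v in sorted(val.items()):
                if isinstance(v, pd.DataFrame):
                    out[f"{key}/{sub}"] = hashlib.sha256(
                        v.round(12).to_csv().encode()).hexdigest()[:16]
    return out


def write_report(bundle: dict, path: str) -> str:
    """Render the bundle as a Markdown report; regeneration is idempotent."""
    lines = [
        "# Synthetic columnar-mapping pipeline report",
        f"\nConfig hash: `{bundle['config_hash']}`",
    ]

    def table(df: pd.DataFrame) -> str:
        return df.round(4).to_markdown(index=False)

    lines += ["\n## 1. Stimulus geometry", table(bundle["geometry_examples"])]
    s = bundle["sdp_summary"]
    lines += [
        "\n## 2. Stop-distance behavior",
        table(bundle["sdp_per_subject"]),
        f"\nRepeated-measures ANOVA (trial effect): "
        f"F({s.df1:.1f}, {s.df2:.1f}) = {s.anova_f:.2f}, p = {s.p_value:.2f} "
        f"(GG eps = {s.gg_epsilon:.2f}); grand mean {s.grand_mean:.1f} cm, "
        f"between-subject SD {s.between_subject_sd:.1f} cm.",
    ]
    lines += ["\n## 3. Radial vs surface-parallel correlations",
              table(bundle["axis_table"]), "", table(bundle["axis_tests"])]
    lines += ["\n## 4. Gray matter vs above-surface control",
              table(bundle["vessel_table"].reset_index(names="subject")),
              "", table(bundle["vessel_tests"])]
    lines += ["\n## 5. Interdigitation and session consistency"]
    if bundle["overlap_curves"]:
        for name, df in bundle["overlap_curves"].items():
            lines += [f"\n### {name}", table(df)]
    else:
        lines += ["\n(no disparity columns in this configuration; overlap "
                  "curves skipped)"]
    lines += ["\nSession consistency:", table(bundle["session_consistency"]),
              "\nPatch counts:", table(bundle["patch_counts"])]
    lines += ["\n## 6. Distance tuning"]
    for ctype, curve in bundle["tuning_curves"].items():
        df = pd.DataFrame({"distance_pct": curve.distances_pct,
                           "mean": curve.mean, "sd": curve.sd, "n": curve.n})
        lines += [f"\n### {ctype} columns "
                  f"(classified: {bundle['tuning_classes'][ctype]})",
                  table(df)]
    lines += ["\n## 7. Rate-model response profiles"]
    for name, prof in bundle["rate_profiles"].items():
        sub = prof.iloc[:: max(1, len(prof) // 10)]
        lines += [f"\n### {name} preset "
                  f"(regime: {bundle['rate_regimes'][name]})", table(sub)]
    lines += ["\n## Recomputed published statistics",
              table(bundle["reported_checks"])]
    text = "\n".join(lines) + "\n"
    with open(path, "w") as fh:
        fh.write(text)
    return text
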