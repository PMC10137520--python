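"""Configuration-driven end-to-end runs.

Reproduces the study's three analyses on synthetic or user-supplied CSV
data: exploratory PCA, NOC-calibrated monitoring charts, and PLS prediction
of quality responses.  Each stage writes plain CSV tables and structured
text model files into the output directory so stages compose through the
filesystem; the returned report only contains numbers recomputable from
those artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import QualitySeries, RGBSeries, SpectraBlock
from .latent import (
    CVScheme,
    duplex_split,
    fit_pca,
    fit_pls,
    rmsecv,
    rmsep,
    select_pca_components,
    vip_scores,
)
from .mspc import chart_table, fit_mspc, flagged_episodes, monitor, noc_calibration_split
from .preprocess import PreprocessState, dop_apply, fit_dop, savitzky_golay
from .synthetic import CampaignConfig, SyntheticCampaign, generate_campaign
from .timeline import align_quality, assemble_dataset, clean_rgb, detect_stops, stop_mask

log = logging.getLogger("procmon")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "load_campaign", "assemble"]


@dataclass
class RunConfig:
    """One pipeline run: exactly one data source plus stage settings."""

    stage: str = "mspc"  # simulate | explore | mspc | predict
    out_dir: str = "procmon_out"
    seed: int = 0
    # data source: either a synthetic campaign config ...
    campaign: CampaignConfig | None = None
    # ... or a directory of spectra.csv / rgb.csv / quality.csv
    csv_dir: str | None = None
    # preprocessing
    sg_window: int = 15
    sg_polyorder: int = 2
    sg_deriv: int = 2
    # MSPC settings
    n_components: int | None = 4  # None = choose by cross-validation
    alpha: float = 0.05
    q_method: str = "jackson_mudholkar"
    cal_fraction: float = 0.65
    # PLS settings
    response: str = "lipids"  # lipids | consistency
    max_lv: int = 10
    cv_splits: int = 10
    split_ratio: float = 0.7
    use_dop: bool | None = None  # default: on for consistency, off for lipids
    dop_components: int = 4
    dop_bandwidth: float | None = None
    # timeline settings
    stop_tolerance: float = 0.0
    stop_min_duration: int = 4
    k_mad: float = 5.0
    residence_lag_s: float | None = None

    def validate(self) -> None:
        if (self.campaign is None) == (self.csv_dir is None):
            raise ValueError("exactly one data source (campaign or csv_dir) required")
        if self.response not in ("consistency", "lipids"):
            raise ValueError("response must be 'consistency' or 'lipids'")


@dataclass
class RunReport:
    stage: str
    summary: dict
    files: list[str] = field(default_factory=list)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"stage": self.stage, "summary": self.summary, "files": self.files}, fh)


def load_campaign(config: RunConfig):
    """Resolve the data source into (spectra, rgb, quality, labels, campaign)."""
    if config.campaign is not None:
        camp = config.campaign
        if camp.seed != config.seed:
            from dataclasses import replace

            camp = replace(camp, seed=config.seed)
        campaign = generate_campaign(camp)
        return campaign.spectra, campaign.rgb, campaign.quality, campaign.labels, campaign
    d = Path(config.csv_dir)
    spectra = SpectraBlock.from_csv(d / "spectra.csv")
    rgb = RGBSeries.from_csv(d / "rgb.csv")
    quality = QualitySeries.from_csv(d / "quality.csv")
    labels = None
    if (d / "labels.csv").exists():
        labels = pd.read_csv(d / "labels.csv", index_col=0, parse_dates=True)
    return spectra, rgb, quality, labels, None


def assemble(config: RunConfig, spectra, rgb, quality, labels):
    """Timeline reconstruction shared by the explore/predict stages."""
    stops = detect_stops(rgb, config.stop_tolerance, config.stop_min_duration)
    mask = clean_rgb(rgb, config.k_mad)
    lag = config.residence_lag_s
    if lag is None:
        lag = (
            config.campaign.residence_lag_s
            if config.campaign is not None
            else 0.0
        )
    alignment = align_quality(spectra.timestamps, quality.timestamps, lag)
    table = assemble_dataset(spectra, rgb, quality, stops, mask, alignment, labels)
    log.info(
        "assembled %d rows (%d matched, %d stops detected, %d frames flagged)",
        len(table),
        len(alignment.pairs),
        len(stops),
        int((~mask).sum()),
    )
    return table, stops, mask, alignment


def _spectra_from_table(table: pd.DataFrame, wavelengths) -> SpectraBlock:
    cols = [f"{w:g}" for w in wavelengths]
    return SpectraBlock(table.index, wavelengths, table[cols].to_numpy(dtype=float))


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute one configured stage and write its artifacts."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spectra, rgb, quality, labels, campaign = load_campaign(config)

    if config.stage == "simulate":
        return _run_simulate(config, out, campaign)
    if config.stage == "explore":
        return _run_explore(config, out, spectra, rgb, quality, labels)
    if config.stage == "mspc":
        return _run_mspc(config, out, spectra, rgb, labels)
    if config.stage == "predict":
        return _run_predict(config, out, spectra, rgb, quality, labels)
    raise ValueError(f"unknown stage {config.stage!r}")


def _run_simulate(config, out, campaign: SyntheticCampaign) -> RunReport:
    if campaign is None:
        raise ValueError("simulate stage needs a synthetic campaign config")
    campaign.write(out)
    summary = {
        "n_time_points": int(campaign.spectra.n_samples),
        "n_quality_records": int(campaign.quality.n_samples),
        "n_stops": len(campaign.config.stop_schedule),
        "n_restart_points": int(campaign.labels["is_restart_anomaly"].sum()),
    }
    report = RunReport("simulate", summary, sorted(p.name for p in out.iterdir()))
    report.save(out / "report.yaml")
    return report


def _run_explore(config, out, spectra, rgb, quality, labels) -> RunReport:
    table, stops, mask, alignment = assemble(config, spectra, rgb, quality, labels)
    block = _spectra_from_table(table, spectra.wavelengths)
    state = PreprocessState(
        methods=["savitzky_golay", "mean_center"],
        sg_window=config.sg_window,
        sg_polyorder=config.sg_polyorder,
        sg_deriv=config.sg_deriv,
    )
    Xp = state.fit_transform(block)
    n_comp = config.n_components or select_pca_components(Xp, 10, config.cv_splits)[0]
    pca = fit_pca(Xp, n_comp)
    scores = pd.DataFrame(
        pca.scores,
        index=block.timestamps,
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )
    for col in ("supplier", "cut", "is_restart_anomaly"):
        if labels is not None and col in table.columns:
            scores[col] = table[col].to_numpy()
    scores.to_csv(out / "pca_scores.csv")
    loadings = pd.DataFrame(
        pca.loadings,
        index=[f"{w:g}" for w in spectra.wavelengths],
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )
    loadings.to_csv(out / "pca_loadings.csv")
    summary = {
        "n_rows": int(len(table)),
        "n_components": int(n_comp),
        "explained_variance_pct": [round(float(v), 3) for v in pca.explained_variance_pct],
        "total_explained_pct": round(float(pca.explained_variance_pct.sum()), 3),
    }
    report = RunReport("explore", summary, ["pca_scores.csv", "pca_loadings.csv"])
    report.save(out / "report.yaml")
    return report


def _run_mspc(config, out, spectra, rgb, labels) -> RunReport:
    stops = detect_stops(rgb, config.stop_tolerance, config.stop_min_duration)
    in_stop = stop_mask(spectra.n_samples, stops)
    non_noc = None
    if labels is not None and "is_restart_anomaly" in labels.columns:
        non_noc = np.flatnonzero(labels["is_restart_anomaly"].to_numpy())
    split = noc_calibration_split(
        spectra.timestamps,
        [(s.start_time, s.end_time) for s in stops],
        config.cal_fraction,
        non_noc_indices=non_noc,
    )
    cal_block = spectra.take(split.calibration_indices)
    state = PreprocessState(
        methods=["savitzky_golay", "mean_center"],
        sg_window=config.sg_window,
        sg_polyorder=config.sg_polyorder,
        sg_deriv=config.sg_deriv,
    )
    if config.n_components is None:
        probe = PreprocessState(
            methods=state.methods,
            sg_window=state.sg_window,
            sg_polyorder=state.sg_polyorder,
            sg_deriv=state.sg_deriv,
        )
        n_comp = select_pca_components(probe.fit_transform(cal_block), 10, config.cv_splits)[0]
    else:
        n_comp = config.n_components
    model = fit_mspc(cal_block, n_comp, config.alpha, config.q_method, preprocess=state)
    model.save(out / "mspc_model.yaml")

    # monitor everything that is not inside a stop, calibration included
    eligible = np.flatnonzero(~in_stop)
    mon_block = spectra.take(eligible)
    points = monitor(mon_block, model)
    table = chart_table(points, model)
    table["in_calibration"] = np.isin(eligible, split.calibration_indices)
    table.to_csv(out / "chart.csv", index=False)

    test_rows = table.loc[~table["in_calibration"]]
    # an episode is a run of >= 3 consecutive flagged samples: a calibrated
    # chart flags only a few non-consecutive points, a process departure a group
    episodes_t2 = flagged_episodes(test_rows["exceeds_T2"].to_numpy(), min_length=3)
    episodes_q = flagged_episodes(test_rows["exceeds_Q"].to_numpy(), min_length=3)
    summary = {
        "n_calibration": int(len(split.calibration_indices)),
        "n_test": int(len(split.test_indices)),
        "n_components": int(n_comp),
        "explained_variance_pct": round(float(model.pca.explained_variance_pct.sum()), 3),
        "t2_limit": round(float(model.t2_limit), 6),
        "q_limit": float(model.q_limit),
        "test_exceed_t2_pct": round(100 * float(test_rows["exceeds_T2"].mean()), 3),
        "test_exceed_q_pct": round(100 * float(test_rows["exceeds_Q"].mean()), 3),
        "n_flagged_episodes_t2": len(episodes_t2),
        "n_flagged_episodes_q": len(episodes_q),
        "flagged_episodes_t2": [[int(a), int(b)] for a, b in episodes_t2],
        "flagged_episodes_q": [[int(a), int(b)] for a, b in episodes_q],
    }
    report = RunReport("mspc", summary, ["mspc_model.yaml", "chart.csv"])
    report.save(out / "report.yaml")
    return report


def _run_predict(config, out, spectra, rgb, quality, labels) -> RunReport:
    table, stops, mask, alignment = assemble(config, spectra, rgb, quality, labels)
    col = "consistency_cm" if config.response == "consistency" else "lipids_pct"
    table = table.loc[np.isfinite(table[col])]
    block = _spectra_from_table(table, spectra.wavelengths)
    y = table[col].to_numpy(dtype=float)

    use_dop = config.use_dop
    if use_dop is None:
        use_dop = config.response == "consistency"

    if use_dop:
        # DOP on raw spectra; only mean centering afterwards (fit_pls centers)
        X_all = block.values
    else:
        X_all = savitzky_golay(
            block, config.sg_window, config.sg_polyorder, config.sg_deriv
        ).values

    split = duplex_split(X_all, config.split_ratio)
    cal, test = split.calibration_indices, split.test_indices
    n_removed = 0
    if "is_restart_anomaly" in table.columns:
        # anomalous (restart) samples are removed from the test set after
        # splitting: their spectra describe residual material, not the
        # product whose quality was measured
        anomalous = table["is_restart_anomaly"].to_numpy(dtype=bool)
        n_removed = int(anomalous[test].sum())
        test = test[~anomalous[test]]
    X_cal, X_test = X_all[cal], X_all[test]
    y_cal, y_test = y[cal], y[test]

    dop = None
    if use_dop:
        dop = fit_dop(X_cal, y_cal, config.dop_components, config.dop_bandwidth)
        X_cal = dop_apply(X_cal, dop)
        X_test = dop_apply(X_test, dop)

    max_lv = min(config.max_lv, X_cal.shape[0] - 2, np.linalg.matrix_rank(X_cal - X_cal.mean(axis=0)))
    curve, n_lv = rmsecv(X_cal, y_cal, max_lv, CVScheme(n_splits=config.cv_splits))
    model = fit_pls(X_cal, y_cal, n_lv)
    err = rmsep(model, X_test, y_test)
    vip = vip_scores(model)
    model.save(out / f"pls_{config.response}.yaml")
    if dop is not None:
        dop.save(out / f"dop_{config.response}.yaml")
    pd.DataFrame(
        {"n_lv": np.arange(1, max_lv + 1), "rmsecv": curve}
    ).to_csv(out / "rmsecv.csv", index=False)
    pd.DataFrame(
        {"wavelength_nm": spectra.wavelengths, "vip": vip}
    ).to_csv(out / "vip.csv", index=False)
    preds = pd.DataFrame(
        {
            "y_measured": y_test,
            "y_predicted": model.predict(X_test),
            "set": "test",
        },
        index=block.timestamps[test],
    )
    preds.to_csv(out / "predictions.csv")
    vip_max_wl = float(spectra.wavelengths[int(np.argmax(vip))])
    summary = {
        "response": config.response,
        "n_rows": int(len(table)),
        "n_calibration": int(len(cal)),
        "n_test": int(len(test)),
        "n_anomalous_removed_from_test": n_removed,
        "dop": bool(use_dop),
        "selected_lv": int(n_lv),
        "rmsecv": round(float(curve[n_lv - 1]), 6),
        "rmsep": round(float(err), 6),
        "vip_max_wavelength_nm": vip_max_wl,
    }
    report = RunReport(
        "predict",
        summary,
        [f"pls_{config.response}.yaml", "rmsecv.csv", "vip.csv", "predictions.csv"],
    )
    report.save(out / "report.yaml")
    return report
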