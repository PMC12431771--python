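"""End-to-end orchestration: stimuli -> session -> analyses -> tables.

A :class:`RunConfig` fully determines a run (including every seed); two
runs with the same config produce identical tables.  The default scale is
reduced relative to a full recording session (80 neurons, 200 resampling
runs) so a complete analysis finishes on a single desktop core; a
full-scale config is a matter of raising ``n_neurons`` and ``runs``.

Every figure-level analysis lands as a tidy CSV in the output directory,
plus a ``report.json`` with the config hash, seed, and the regenerating
command for each table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import codingmetrics, decoding, responses, sfmetrics, simdata, stimgen
from .responses import trial_mask
from .stimgen import BAND_LABELS

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis", "simulate_to_dir"]


@dataclass
class RunConfig:
    """Serializable description of a complete analysis run."""

    seed: int = 0
    # stimuli
    n_base_images: int = 15
    image_side: int = 128
    butterworth_order: int = 4
    luminance: float = 0.5
    contrast: float = 0.0314
    # session
    n_blocks: int = 15
    n_neurons: int = 80
    profile_mix: dict[str, float] = field(
        default_factory=lambda: dict(simdata.DEFAULT_PROFILE_MIX)
    )
    trial_gain_sd: float = 0.2
    # analysis
    t1: tuple[float, float] = (70.0, 170.0)
    t2: tuple[float, float] = (170.0, 270.0)
    time_range: tuple[float, float] = (-60.0, 350.0)
    runs: int = 200
    timecourse_runs: int = 50
    single_neuron_runs: int = 50
    subpop_window: int = 20
    subpop_runs: int = 30
    cmi_bins: int = 10
    cmi_shuffles: int = 10
    shrinkage: str = "auto"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_mapping(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        for key in ("t1", "t2", "time_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, out_dir: Path, name: str, report: dict) -> None:
    path = out_dir / name
    df.to_csv(path, index=False)
    report["tables"][name] = {
        "rows": len(df),
        "regenerate": f"sfcode all --config config.yaml --out {out_dir.name}",
    }


def simulate_to_dir(config: RunConfig, out_dir: str | Path) -> simdata.SpikeSession:
    """Build stimuli and simulate a session, persisting both."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    bases = stimgen.make_texture_bases(
        config.n_base_images, config.image_side, rng
    )
    records = stimgen.build_stimulus_set(
        bases,
        bands=stimgen.default_bands(config.butterworth_order),
        targets=stimgen.NormTargets(config.luminance, config.contrast),
        rng=rng,
    )
    manifest = stimgen.records_manifest(records)
    manifest.to_csv(out / "stimuli.csv", index=False)
    population = simdata.make_population(
        config.n_neurons, config.profile_mix, rng
    )
    session = simdata.simulate_session(
        population,
        manifest[["stim_id", "base_id", "category", "band", "scrambled"]]
        .drop_duplicates("stim_id"),
        simdata.SessionSpec(n_blocks=config.n_blocks),
        rng,
        trial_gain_sd=config.trial_gain_sd,
    )
    simdata.write_session_hdf5(session, out / "session.h5")
    pd.DataFrame(
        {
            "neuron_id": [n.neuron_id for n in population],
            "profile": [n.profile.label for n in population],
            "baseline_rate": [n.baseline_rate for n in population],
            "response_gain": [n.response_gain for n in population],
            "category_gain": [n.category_gain for n in population],
        }
    ).to_csv(out / "population.csv", index=False)
    return session


def run_full_analysis(
    config: RunConfig,
    out_dir: str | Path,
    session: simdata.SpikeSession | None = None,
) -> dict:
    """Execute every figure-level analysis and write its tables.

    Stages: stimulus/session generation (or reuse), response tensor and
    z-scoring, SF decoding time course with per-band recalls and onsets,
    preferred-SF time course with interval band tuning and dominant-band
    fractions, SF profiles with per-profile separability, sorted
    sub-population scatter, single-vs-population decoding correlations,
    and SNC / CMI / weight-sparseness comparisons of SF vs category.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "tables": {},
    }
    config.to_yaml(out / "config.yaml")
    if session is None:
        session = simulate_to_dir(config, out)
    rng = np.random.default_rng(config.seed + 1)

    logger.info("binning rates")
    tensor = responses.bin_rates(session)
    screen = responses.responsiveness_screen(tensor)
    tensor = tensor.select_neurons(screen)
    bstats = responses.baseline_stats(tensor)
    ztensor, _excluded = responses.zscore(tensor, bstats)
    report["n_responsive_neurons"] = int(screen.sum())

    scr_mask = trial_mask(tensor.manifest, bands=list(BAND_LABELS), scrambled=True)
    z_scr = ztensor.select_trials(scr_mask)
    raw_scr = tensor.select_trials(scr_mask)
    y_band = z_scr.manifest["band"].to_numpy()
    lsf_hsf = np.isin(y_band, ["R1", "R2", "R4", "R5"])
    y_binary_sf = np.where(np.isin(y_band[lsf_hsf], ["R1", "R2"]), "LSF", "HSF")
    cat_mask = trial_mask(
        tensor.manifest, bands=["intact"], scrambled=False,
        categories=["face", "nonface"],
    )
    z_cat = ztensor.select_trials(cat_mask)
    y_cat = z_cat.manifest["category"].to_numpy()

    # --- SF decoding time course, recalls, onsets -----------------------
    logger.info("SF decoding time course")
    tc = decoding.sf_decoding_timecourse(
        z_scr, runs=config.timecourse_runs, rng=rng,
        time_range=config.time_range, shrinkage=config.shrinkage,
    )
    _write(tc.summary(), out, "sf_decoding_timecourse.csv", report)
    onset_rows = [
        {
            "band": "all",
            "onset_ms": decoding.onset_time(tc.times, tc.accuracies).onset_ms,
        }
    ]
    for k, band in enumerate(tc.classes):
        res = decoding.onset_time(tc.times, tc.recalls[:, :, k])
        onset_rows.append({"band": band, "onset_ms": res.onset_ms})
    _write(pd.DataFrame(onset_rows), out, "sf_onsets.csv", report)

    X_t1 = z_scr.window_mean(*config.t1)
    cv_t1 = decoding.decode_cv(
        X_t1, y_band, runs=config.runs, rng=rng, shrinkage=config.shrinkage
    )
    _write(
        pd.DataFrame(
            {
                "band": cv_t1.classes,
                "recall_mean": cv_t1.mean_recalls,
                "recall_sd": cv_t1.recalls.std(axis=0, ddof=1),
                "accuracy_mean": cv_t1.mean_accuracy,
            }
        ),
        out, "sf_recall_t1.csv", report,
    )

    # --- preferred SF and band tuning ----------------------------------
    logger.info("preferred SF")
    _write(sfmetrics.preferred_sf_timecourse(raw_scr), out,
           "psf_timecourse.csv", report)
    tuning_rows = []
    for name, (lo, hi) in (("T1", config.t1), ("T2", config.t2)):
        resp = raw_scr.window_mean(lo, hi)
        dom_counts = {b: 0 for b in BAND_LABELS}
        n_dom = 0
        band_of = raw_scr.manifest["band"].to_numpy()
        for i in range(raw_scr.n_neurons):
            groups = [resp[band_of == b, i] for b in BAND_LABELS]
            best = sfmetrics.dominant_band(groups)
            if best is not None:
                dom_counts[best] += 1
                n_dom += 1
        for b in BAND_LABELS:
            vals = resp[band_of == b].mean(axis=0)
            tuning_rows.append(
                {
                    "interval": name,
                    "band": b,
                    "mean_rate": float(vals.mean()),
                    "sem_rate": float(vals.std(ddof=1) / np.sqrt(len(vals))),
                    "dominant_fraction": dom_counts[b] / n_dom if n_dom else np.nan,
                }
            )
    _write(pd.DataFrame(tuning_rows), out, "band_tuning.csv", report)

    # --- profiles and per-profile separability -------------------------
    logger.info("SF profiles")
    profiles = sfmetrics.classify_population_profiles(tensor, window=config.t1)
    _write(profiles, out, "profiles.csv", report)
    si_rows = []
    for label in ("LP", "HP", "U", "IU"):
        ids = profiles.loc[profiles["label"] == label, "neuron_id"].to_numpy()
        if len(ids) < 2:
            continue
        sel = np.isin(np.asarray(ztensor.neuron_ids), ids)
        sub = ztensor.select_neurons(sel)
        for cat in ("face", "nonface"):
            m_cat = trial_mask(
                sub.manifest, bands=["intact"], scrambled=False, categories=[cat]
            )
            m_scr = trial_mask(sub.manifest, bands=["intact"], scrambled=True)
            both = m_cat | m_scr
            X = sub.select_trials(both).window_mean(*config.t1)
            lab = np.where(m_cat[both], cat, "scrambled")
            si = codingmetrics.separability_index(X, lab)
            si_rows.append(
                {
                    "profile": label, "contrast": f"{cat}_vs_scrambled",
                    "si": si.si, "n_neurons": int(sel.sum()),
                }
            )
    _write(pd.DataFrame(si_rows), out, "profile_si.csv", report)

    # --- single-neuron skill, sorted sub-populations, correlations ------
    logger.info("single-neuron decoding")
    sf_single = np.array(
        [
            decoding.decode_cv(
                X_t1[:, [i]], y_band, runs=config.single_neuron_runs, rng=rng
            ).mean_accuracy
            for i in range(X_t1.shape[1])
        ]
    )
    X_cat_t1 = z_cat.window_mean(*config.t1)
    cat_single = np.array(
        [
            decoding.decode_cv(
                X_cat_t1[:, [i]], y_cat, runs=config.single_neuron_runs,
                rng=rng, balance=True,
            ).mean_accuracy
            for i in range(X_cat_t1.shape[1])
        ]
    )
    from scipy import stats as sps

    r_single, p_single = sps.pearsonr(sf_single, cat_single)
    subpop = decoding.sorted_subpopulation_analysis(
        sf_single,
        X_t1, y_band, X_cat_t1, y_cat,
        window=min(config.subpop_window, len(sf_single)),
        runs=config.subpop_runs, rng=rng, shrinkage=config.shrinkage,
    )
    _write(subpop.table, out, "subpopulations_sf_sorted.csv", report)

    # population weights for the weight scatter
    _, w_sf = decoding.decode_cv(
        X_t1[lsf_hsf], y_binary_sf, runs=config.subpop_runs, rng=rng,
        collect_weights=True, shrinkage=config.shrinkage,
    )
    _, w_cat = decoding.decode_cv(
        X_cat_t1, y_cat, runs=config.subpop_runs, rng=rng,
        collect_weights=True, balance=True, shrinkage=config.shrinkage,
    )
    mean_w_sf = w_sf.mean(axis=0)
    mean_w_cat = w_cat.mean(axis=0)
    r_w, p_w = sps.pearsonr(np.abs(mean_w_sf), np.abs(mean_w_cat))
    _write(
        pd.DataFrame(
            {
                "neuron_id": np.asarray(ztensor.neuron_ids),
                "sf_single_accuracy": sf_single,
                "category_single_accuracy": cat_single,
                "sf_weight": mean_w_sf,
                "category_weight": mean_w_cat,
            }
        ),
        out, "single_vs_population.csv", report,
    )
    report["correlations"] = {
        "single_sf_vs_category_r": float(r_single),
        "single_sf_vs_category_p": float(p_single),
        "weights_sf_vs_category_r": float(r_w),
        "weights_sf_vs_category_p": float(p_w),
        "subpop_sf_sorted_sf_r": subpop.corr_sf,
        "subpop_sf_sorted_category_r": subpop.corr_category,
    }

    # --- SNC, CMI, sparseness ------------------------------------------
    logger.info("SNC / CMI / sparseness")
    X_bin_sf = X_t1[lsf_hsf]
    snc_sf = codingmetrics.snc(
        X_bin_sf, y_binary_sf, runs=max(10, config.runs // 10), rng=rng,
        shrinkage=config.shrinkage,
    )
    snc_cat = codingmetrics.snc(
        X_cat_t1, y_cat, runs=max(10, config.runs // 10), rng=rng,
        balance=True, shrinkage=config.shrinkage,
    )
    _write(
        pd.DataFrame(
            {
                "neuron_id": np.asarray(ztensor.neuron_ids),
                "snc_sf_pp": snc_sf.drops_pp,
                "snc_category_pp": snc_cat.drops_pp,
            }
        ),
        out, "snc.csv", report,
    )
    raw_bin_sf = raw_scr.window_mean(*config.t1)[lsf_hsf]
    cmi_sf = codingmetrics.cmi_pairs(
        raw_bin_sf, y_binary_sf, n_bins=config.cmi_bins,
        n_shuffles=config.cmi_shuffles, rng=rng,
    )
    raw_cat = tensor.select_trials(cat_mask).window_mean(*config.t1)
    cmi_cat = codingmetrics.cmi_pairs(
        raw_cat, y_cat, n_bins=config.cmi_bins,
        n_shuffles=config.cmi_shuffles, rng=rng,
    )
    _write(
        pd.DataFrame(
            {
                "condition": ["SF", "category"],
                "mean_raw_cmi": [cmi_sf.mean_offdiag(False), cmi_cat.mean_offdiag(False)],
                "mean_corrected_cmi": [cmi_sf.mean_offdiag(), cmi_cat.mean_offdiag()],
            }
        ),
        out, "cmi_summary.csv", report,
    )
    sp_sf = codingmetrics.sparseness_timecourse(
        z_scr.select_trials(lsf_hsf), y_binary_sf,
        runs=config.timecourse_runs, rng=rng, time_range=config.time_range,
        shrinkage=config.shrinkage,
    ).rename(columns=lambda c: c.replace("sparseness", "sf_sparseness"))
    sp_cat = codingmetrics.sparseness_timecourse(
        z_cat, y_cat, runs=config.timecourse_runs, rng=rng, balance=True,
        time_range=config.time_range, shrinkage=config.shrinkage,
    ).rename(columns=lambda c: c.replace("sparseness", "category_sparseness"))
    _write(sp_sf.merge(sp_cat, on="time"), out, "sparseness_timecourse.csv",
           report)

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
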