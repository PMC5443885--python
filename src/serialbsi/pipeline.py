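"""End-to-end orchestration of the synthetic serial-MRI study.

Stages: simulate phantoms and cohorts → measure BSI volume change → fit the
direct-change mixed model with the residual-variance likelihood-ratio test →
paired agreement and QC statistics → trial sample-size estimation.  Every
stage draws its randomness from seeds derived from the single config seed,
and every tabular output is written deterministically, so a rerun with the
same config reproduces the outputs byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import bsi as _bsi
from . import io as _io
from . import lmm as _lmm
from . import power as _power
from . import stats as _stats
from .config import RunConfig, config_to_yaml
from .phantom import (ACCELERATED, NON_ACCELERATED, SCAN_TYPES, NoiseSpec,
                      PhantomSpec, add_acquisition_noise, add_motion_artifact,
                      make_phantom_pair, phantom_visit_series, simulate_cohort,
                      simulate_qc_labels)

_STAGES = ("phantom", "imaging", "cohort", "qc", "stats", "power")


def derive_seed(master: int, *key: int) -> int:
    """Deterministic child seed below 2**31."""
    ss = np.random.SeedSequence([int(master), *map(int, key)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# structure-level measurement on a normalized pair

def _normalized_with_centroids(pair: _bsi.ImagePair, brain_union, settings):
    c_b = _bsi.tissue_means_kmeans(pair.baseline, brain_union, k=3)
    c_f = _bsi.tissue_means_kmeans(pair.followup, brain_union, k=3)
    norm = _bsi.normalise_pair(pair, c_b, c_f, settings.target_means)
    nc = 0.5 * (_bsi.apply_affine(c_b, c_b, settings.target_means)
                + _bsi.apply_affine(c_f, c_f, settings.target_means))
    return norm, nc  # nc = normalized (CSF, GM, WM) centroids


def measure_structures(pair: _bsi.ImagePair, masks: dict, settings) -> dict:
    """KN-BSI (brain), fixed-window BSI (ventricle) and double-window BSI
    (hippocampus) on one co-registered pair.  Returns structure → BsiResult."""
    out = {}
    mb, mf = masks["brain"]
    out["brain"] = _bsi.kn_bsi(pair, mb, mf, settings.dilate, settings.erode,
                               settings.target_means, settings.window_fraction)
    union = np.asarray(mb, bool) | np.asarray(mf, bool)
    norm, nc = _normalized_with_centroids(pair, union, settings)
    if "ventricle" in masks:
        vb, vf = masks["ventricle"]
        out["ventricle"] = _bsi.fixed_window_bsi(
            norm, vb, vf, _bsi.IntensityWindow(*settings.ventricle_window),
            settings.dilate, settings.erode)
    if "hippocampus" in masks:
        hb, hf = masks["hippocampus"]
        out["hippocampus"] = _bsi.double_window_bsi(
            norm, hb, hf,
            _bsi.IntensityWindow(nc[0], nc[1]),
            _bsi.IntensityWindow(nc[1], nc[2]),
            dilate=settings.dilate, erode=settings.erode)
    return out


# ---------------------------------------------------------------------------
# image-based cohort

def simulate_imaging_cohort(config: RunConfig, n_subjects: int | None = None
                            ) -> tuple[pd.DataFrame, dict]:
    """Generate phantom visit series per subject, acquire both scan types,
    and measure whole-brain KN-BSI for every visit pair.

    Each subject's true annualised loss rate is N(rate_mean, rate_sd²) and
    per-visit ml perturbations of the brain volume realize the visit random
    effects, so a measured change j→k carries rate·t − u_j + u_k plus
    BSI measurement error.  Returns the change table (cohort CSV schema) and
    the per-subject truth.
    """
    img = config.imaging
    n = n_subjects if n_subjects is not None else img.n_subjects
    spec = config.phantom
    t = np.asarray(img.visit_times)
    master = derive_seed(config.seed, 1)
    rng = np.random.default_rng(master)
    v0 = None
    rows = []
    truth = {"rates": [], "visit_effects": []}
    snr = {ACCELERATED: (img.snr_accelerated, img.snr_gradient_accelerated),
           NON_ACCELERATED: (img.snr_non_accelerated, 0.0)}
    motion = {ACCELERATED: img.motion_severity_accelerated,
              NON_ACCELERATED: img.motion_severity_non_accelerated}
    base_vol = (4.0 / 3.0) * np.pi * spec.brain_radius ** 3 / 1000.0
    for i in range(n):
        rate = rng.normal(img.rate_mean_ml_yr, img.rate_sd_ml_yr)
        u = rng.normal(0.0, img.visit_sd_ml, size=len(t))
        volumes = np.maximum(base_vol - rate * t + u, 0.5 * base_vol)
        images, brain_masks, realized = phantom_visit_series(spec, list(volumes))
        truth["rates"].append(rate)
        truth["visit_effects"].append(u.tolist())
        noisy = {}
        for sc, st in enumerate(SCAN_TYPES):
            for j, im in enumerate(images):
                seed = derive_seed(config.seed, 1, i, sc, j)
                ns = NoiseSpec(scan_type=st, snr_center=snr[st][0],
                               snr_gradient=snr[st][1], seed=seed)
                vol = add_acquisition_noise(im, ns, spec.voxel_size)
                if motion[st] > 0:
                    vol = add_motion_artifact(vol, motion[st], seed=seed + 1)
                noisy[(st, j)] = vol
        for j, k in itertools.combinations(range(len(t)), 2):
            for st in SCAN_TYPES:
                pair = _bsi.ImagePair(noisy[(st, j)], noisy[(st, k)],
                                      spec.voxel_volume_ml)
                res = _bsi.kn_bsi(pair, brain_masks[j], brain_masks[k],
                                  config.bsi.dilate, config.bsi.erode,
                                  config.bsi.target_means,
                                  config.bsi.window_fraction)
                rows.append((f"P{i + 1:04d}", "AD", j, k, t[k] - t[j], st,
                             res.value_ml))
    table = pd.DataFrame(rows, columns=_io.COHORT_COLUMNS)
    return table, truth


# ---------------------------------------------------------------------------
# the full study

def _fit_report(records: pd.DataFrame) -> dict:
    stat, df, p, fit_common, fit_sep = _lmm.lrt_residual_variances(records)
    report = {
        "n_records": fit_sep.n_records,
        "n_subjects": fit_sep.n_subjects,
        "beta": fit_sep.beta,
        "beta_se": fit_sep.beta_se,
        "var_slope": fit_sep.var_slope,
        "var_visit": fit_sep.var_visit,
        "var_resid": fit_sep.var_resid,
        "loglik_separate": fit_sep.loglik,
        "loglik_common": fit_common.loglik,
        "lrt": {"chi2": stat, "df": df, "p": p},
        "converged": fit_sep.converged,
    }
    rates = {}
    for dx in fit_sep.present_dx:
        for st in SCAN_TYPES:
            r, se = _lmm.adjusted_group_rates(fit_sep, dx, st)
            rates[f"{dx}/{st}"] = {"rate_ml_yr": r, "se": se}
    report["adjusted_rates"] = rates
    return report


def _round_floats(obj, nd=10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), nd)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _write_json(data: dict, path: Path) -> None:
    path.write_text(json.dumps(_round_floats(data), indent=2, sort_keys=True)
                    + "\n")


def run_synthetic_study(config: RunConfig, outdir) -> dict:
    """Run the full synthetic study; returns the manifest (also written).

    Outputs under ``outdir``: phantom NIfTIs and structure BSI table, the
    imaging-cohort and generative-cohort change CSVs, mixed-model fit reports
    with the residual-variance LRT, paired agreement and QC reports, and the
    sample-size table.  ``run.log`` records wall times; ``manifest.json``
    records the config hash, every derived seed and the SHA-256 of every
    table, and is byte-identical across reruns of the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = []
    manifest: dict = {"config_yaml_sha256": None, "seeds": {}, "outputs": {}}
    cfg_yaml = config_to_yaml(config)
    (outdir / "config.yaml").write_text(cfg_yaml)
    import hashlib
    manifest["config_yaml_sha256"] = hashlib.sha256(cfg_yaml.encode()).hexdigest()

    def log(stage, start):
        log_lines.append(f"{stage}: {time.perf_counter() - start:.2f}s")

    # -- stage 1: demo phantom pair, all three structures -------------------
    t0 = time.perf_counter()
    spec = dataclasses.replace(config.phantom, seed=derive_seed(config.seed, 0))
    manifest["seeds"]["phantom"] = spec.seed
    pair, masks, truth = make_phantom_pair(spec)
    for name, vol in (("phantom_baseline", pair.baseline),
                      ("phantom_followup", pair.followup)):
        _io.save_nifti(vol, outdir / f"{name}.nii.gz", spec.voxel_size)
    for sname, (m0, m1) in masks.items():
        _io.save_nifti(m0.astype(np.uint8), outdir / f"mask_{sname}_base.nii.gz",
                       spec.voxel_size)
        _io.save_nifti(m1.astype(np.uint8), outdir / f"mask_{sname}_follow.nii.gz",
                       spec.voxel_size)
    noise = NoiseSpec(scan_type=ACCELERATED,
                      snr_center=config.imaging.snr_accelerated,
                      snr_gradient=config.imaging.snr_gradient_accelerated,
                      seed=derive_seed(config.seed, 0, 1))
    noisy = _bsi.ImagePair(
        add_acquisition_noise(pair.baseline, noise, spec.voxel_size),
        add_acquisition_noise(
            pair.followup,
            dataclasses.replace(noise, seed=derive_seed(config.seed, 0, 2)),
            spec.voxel_size),
        pair.voxel_volume)
    results = measure_structures(noisy, masks, config.bsi)
    bsi_rows = []
    for sname, res in results.items():
        w = res.windows
        bsi_rows.append(("PHANTOM", sname, ACCELERATED, 0, 1, res.value_ml,
                         res.n_boundary_voxels, w[0].lo, w[-1].hi))
    bsi_df = pd.DataFrame(bsi_rows, columns=_io.BSI_COLUMNS)
    _io.write_table(bsi_df, outdir / "phantom_bsi.csv")
    _write_json({"truth_ml": truth}, outdir / "phantom_truth.json")
    log("phantom", t0)

    # -- stage 2: imaging cohort (brain KN-BSI) -----------------------------
    t0 = time.perf_counter()
    manifest["seeds"]["imaging"] = derive_seed(config.seed, 1)
    imaging_table, imaging_truth = simulate_imaging_cohort(config)
    _io.write_table(imaging_table, outdir / "imaging_cohort.csv")
    _write_json({"rate_mean_ml_yr": config.imaging.rate_mean_ml_yr,
                 "rates": imaging_truth["rates"]},
                outdir / "imaging_truth.json")
    log("imaging", t0)

    # -- stage 3: generative cohort + mixed-model fits ----------------------
    t0 = time.perf_counter()
    cohort_seed = derive_seed(config.seed, 2)
    manifest["seeds"]["cohort"] = cohort_seed
    cspec = dataclasses.replace(config.cohort, seed=cohort_seed)
    cohort = simulate_cohort(cspec)
    _io.write_table(cohort, outdir / "cohort.csv")
    reports = {"generative_cohort_brain": _fit_report(cohort)}
    imaging_single_dx = imaging_table.assign(diagnosis="AD")
    reports["imaging_cohort_brain"] = _fit_report(imaging_single_dx)
    _write_json(reports, outdir / "lmm_report.json")
    log("cohort", t0)

    # -- stage 4: QC comparison ---------------------------------------------
    t0 = time.perf_counter()
    st = config.stats
    qc_seed = derive_seed(config.seed, 3)
    manifest["seeds"]["qc"] = qc_seed
    qc = simulate_qc_labels(st.qc_n, st.qc_p_fail_a, st.qc_p_fail_na,
                            st.qc_odds_ratio, seed=qc_seed)
    _io.write_table(qc, outdir / "qc_labels.csv")
    table = _stats.PairedBinary.from_fail_flags(
        qc["fail_accelerated"], qc["fail_non_accelerated"])
    b_stat, mc_p = _stats.mcnemar_paired_proportions(table, method="exact")
    rng = np.random.default_rng(derive_seed(config.seed, 3, 1))
    initial = qc["fail_accelerated"].to_numpy()
    rerate = initial ^ (rng.random(len(initial)) < st.rerate_flip_prob)
    kappa, agreement = _stats.cohen_kappa(initial, rerate)
    _write_json({
        "paired_counts": {"a": table.a, "b": table.b, "c": table.c,
                          "d": table.d},
        "fail_rate_accelerated": float(qc["fail_accelerated"].mean()),
        "fail_rate_non_accelerated": float(qc["fail_non_accelerated"].mean()),
        "mcnemar": {"b": b_stat, "p": mc_p, "method": "exact"},
        "rerating": {"kappa": kappa, "agreement": agreement},
    }, outdir / "qc_report.json")
    log("qc", t0)

    # -- stage 5: paired agreement on measured changes ----------------------
    t0 = time.perf_counter()
    wide = imaging_table.pivot_table(
        index=["subject_id", "visit_j", "visit_k"], columns="scan_type",
        values="y_ml").dropna()
    sample = _stats.PairedSample(wide[NON_ACCELERATED].to_numpy(),
                                 wide[ACCELERATED].to_numpy())
    mean_diff, ci, p = _stats.paired_mean_test(sample)
    pit_stat, pit_p = _stats.pitman_variance_test(sample)
    loa = _stats.limits_of_agreement(sample)
    _write_json({
        "n_pairs": sample.n,
        "paired_t": {"mean_diff_ml": mean_diff, "ci95": list(ci), "p": p},
        "pitman": {"stat": pit_stat, "p": pit_p},
        "limits_of_agreement_ml": {"mean": loa[0], "lower": loa[1],
                                   "upper": loa[2]},
    }, outdir / "agreement_report.json")
    log("stats", t0)

    # -- stage 6: sample sizes ----------------------------------------------
    t0 = time.perf_counter()
    power_seed = derive_seed(config.seed, 4)
    manifest["seeds"]["power"] = power_seed
    last = len(config.imaging.visit_times) - 1
    full = imaging_table[(imaging_table.visit_j == 0)
                         & (imaging_table.visit_k == last)]
    rates = full.pivot_table(index="subject_id", columns="scan_type",
                             values="y_ml").dropna()
    t_full = config.imaging.visit_times[-1]
    ra = (rates[ACCELERATED] / t_full).to_numpy()
    rn = (rates[NON_ACCELERATED] / t_full).to_numpy()
    template = _power.PowerSpec(mu=1.0, sigma=1.0)
    res_a = _power.bootstrap_sample_size_ci(ra, template, st.n_boot, power_seed)
    res_n = _power.bootstrap_sample_size_ci(rn, template, st.n_boot,
                                            power_seed + 1)
    n_a, n_na, diff, dci = _power.compare_protocol_sample_sizes(
        ra, rn, template, st.n_boot, power_seed + 2)
    _write_json({
        "reduction": template.reduction,
        "accelerated": dataclasses.asdict(res_a),
        "non_accelerated": dataclasses.asdict(res_n),
        "difference_non_accel_minus_accel": {"n": diff, "ci95": list(dci)},
    }, outdir / "sample_size_report.json")
    log("power", t0)

    for f in sorted(outdir.glob("*.csv")) + sorted(outdir.glob("*.json")):
        if f.name == "manifest.json":
            continue
        manifest["outputs"][f.name] = _io.sha256_of(f)
    _write_json(manifest, outdir / "manifest.json")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return manifest
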