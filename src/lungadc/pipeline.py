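"""End-to-end pipeline: segmentation -> ADC -> regional -> SNR -> statistics.

``run_pipeline`` consumes a flat config (see :mod:`lungadc.io`) in one of
three modes:

* ``phantom`` — generate a synthetic lung, simulate a paired NDW/DW
  acquisition, and analyse it against its ground truth;
* ``fixture`` — recompute the cohort summary statistics from the bundled
  per-subject table;
* ``files`` — analyse NDW/DW (and optionally CT) volumes from disk.

Outputs are written to the configured directory: NIfTI maps, a per-subject
metrics CSV, a text statistics report, and a log recording the tool
version and seed. All outputs are regenerated bit-identically from
(config, seed); report files carry no timestamps.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adc import compute_adc_map, mean_adc
from .ct import ct_density_metrics
from .errors import ConfigError
from .io import CONFIG_SCHEMA, load_config, write_volume
from .phantom import Lesion, PhantomSpec, generate_ct_phantom, simulate_from_spec
from .regional import regional_metrics
from .segmentation import kmeans_segment
from .snr import compute_snr
from .stats import cohort_report
from .subjects import cohort_dataframe
from .volume import DWAcquisition, LungMask

log = logging.getLogger("lungadc")


def run_pipeline(config: str | Path | dict, output_dir: str | Path | None = None,
                 seed: int | None = None) -> dict:
    """Execute the configured analysis and write its outputs.

    Returns a dict of the headline results (also serialised to disk).
    ``output_dir`` and ``seed`` override the config values.
    """
    cfg = dict(config) if isinstance(config, dict) else load_config(config)
    unknown = sorted(set(cfg) - set(CONFIG_SCHEMA))
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    for key, default in CONFIG_SCHEMA.items():
        cfg.setdefault(key, default)
    if output_dir is not None:
        cfg["output_dir"] = str(output_dir)
    if seed is not None:
        cfg["seed"] = int(seed)

    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)

    mode = cfg["mode"]
    if mode == "phantom":
        result = _run_phantom(cfg, out)
    elif mode == "fixture":
        result = _run_fixture(cfg, out)
    elif mode == "files":
        result = _run_files(cfg, out)
    else:
        raise ConfigError(f"mode must be phantom|fixture|files; got {mode!r}")

    (out / "run.log").write_text(
        f"lungadc {__version__}\nmode: {mode}\nseed: {cfg['seed']}\n"
    )
    return result


def _analyse_acquisition(acq: DWAcquisition, cfg: dict, out: Path,
                         mask: LungMask | None = None) -> dict:
    """Shared segmentation -> ADC -> regional -> SNR stage."""
    if mask is None:
        n_distinct = np.unique(np.nan_to_num(acq.ndw.data)).size
        k = min(int(cfg["kmeans_k"]), n_distinct)
        mask = kmeans_segment(acq.ndw, k=k, seed=cfg["seed"])
    adc_map = compute_adc_map(acq, mask, negative_policy=cfg["negative_adc_policy"])
    regional = regional_metrics(adc_map, mask)
    try:
        snr_ndw = compute_snr(acq.ndw, mask, cfg["snr_noise_definition"],
                              seed=cfg["seed"]).value
        snr_dw = compute_snr(acq.dw, mask, cfg["snr_noise_definition"],
                             seed=cfg["seed"]).value
    except Exception as exc:  # noiseless input: SNR undefined, not fatal
        log.info("SNR stage skipped: %s", exc)
        snr_ndw = snr_dw = float("nan")

    write_volume(adc_map.to_volume(), out / "adc_map.nii")
    write_volume(mask, out / "lung_mask.nii")
    sup, mid, inf = regional.roi_means
    metrics = {
        "gas": acq.gas, "b_value": acq.b_value,
        "mean_adc": mean_adc(adc_map),
        "ap_slope": regional.ap.slope, "ap_intercept": regional.ap.intercept,
        "roi_superior": sup, "roi_middle": mid, "roi_inferior": inf,
        "delta_si": regional.delta_si,
        "snr_ndw": snr_ndw, "snr_dw": snr_dw,
        "lung_voxels": mask.voxel_count,
    }
    return metrics


def _run_phantom(cfg: dict, out: Path) -> dict:
    lesions = tuple(Lesion((int(a), int(s), int(c)), float(r), float(v))
                    for a, s, c, r, v in cfg["lesions"])
    spec = PhantomSpec(
        shape=tuple(cfg["grid_shape"]), spacing=tuple(cfg["spacing_mm"]),
        baseline_adc=cfg["baseline_adc"], ap_slope=cfg["ap_slope"],
        si_offset=cfg["si_offset"], lesions=lesions,
        s0_level=cfg["s0_level"], noise_sigma=cfg["noise_sigma"],
        gas=cfg["gas"], noise_model=cfg["noise_model"], seed=cfg["seed"],
    )
    acq, mask, truth = simulate_from_spec(spec, cfg["b_value"])
    metrics = _analyse_acquisition(acq, cfg, out)
    metrics.update({
        "true_mean_adc": truth.whole_lung_mean,
        "true_ap_slope": truth.ap_slope,
    })

    if cfg["ct_frac_below_950"] is not None:
        hu, ct_mask = generate_ct_phantom(float(cfg["ct_frac_below_950"]),
                                          int(cfg["ct_n_voxels"]), cfg["seed"])
        ct = ct_density_metrics(hu, ct_mask)
        metrics.update({"ra950_pct": ct.ra950_pct, "ra910_pct": ct.ra910_pct,
                        "ra856_pct": ct.ra856_pct, "hu15_hu": ct.hu15_hu,
                        "ct_emphysema": ct.emphysema})

    pd.DataFrame([metrics]).to_csv(out / "metrics.csv", index=False)
    lines = ["phantom analysis", "================"] + [
        f"{k}: {v}" for k, v in metrics.items()
    ]
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return metrics


def _run_fixture(cfg: dict, out: Path) -> dict:
    df = cohort_dataframe()
    report = cohort_report(df)
    report.group_summary.to_csv(out / "group_summary.csv", index=False)
    report.group_tests.to_csv(out / "group_tests.csv", index=False)
    report.correlations.to_csv(out / "correlations.csv", index=False)
    reg_df = pd.DataFrame([vars(r) for r in report.regression.rows])
    reg_df.to_csv(out / "regression.csv", index=False)

    lines = ["cohort statistics", "================="]
    for _, row in report.group_summary.iterrows():
        if row["n"]:
            lines.append(f"{row['group']:22s} {row['metric']:16s} n={row['n']:2d} "
                         f"mean={row['mean']:.4g} sd={row['sd']:.4g}")
    lines.append("")
    for _, row in report.group_tests.iterrows():
        lines.append(f"never vs COPD {row['metric']:16s} U={row['U']:.1f} "
                     f"p={row['p']:.4g}")
    lines.append("")
    for _, row in report.correlations.iterrows():
        lines.append(f"{row['ct_metric']:14s} vs {row['adc_metric']:16s} "
                     f"r={row['r']:+.2f} p={row['p_raw']:.4g} "
                     f"p_holm={row['p_holm']:.4g} (n={row['n']})")
    lines.append("")
    for r in report.regression.rows:
        lines.append(f"regression {r.name:16s} coef={r.coef:.2f} se={r.se:.2f} "
                     f"t={r.t:.2f} p={r.p:.4g}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return {"report": report}


def _run_files(cfg: dict, out: Path) -> dict:
    from .io import read_volume

    if not cfg["ndw_path"] or not cfg["dw_path"]:
        raise ConfigError("files mode requires ndw_path and dw_path")
    ndw = read_volume(cfg["ndw_path"], "signal")
    dw = read_volume(cfg["dw_path"], "signal")
    acq = DWAcquisition(ndw, dw, float(cfg["b_value"]), cfg["gas"])
    metrics = _analyse_acquisition(acq, cfg, out)

    if cfg["ct_path"] and cfg["ct_mask_path"]:
        hu = read_volume(cfg["ct_path"], "hu")
        ct_mask_vol = read_volume(cfg["ct_mask_path"], "signal")
        ct_mask = LungMask(ct_mask_vol.data > 0, ct_mask_vol.spacing)
        ct = ct_density_metrics(hu, ct_mask)
        metrics.update({"ra950_pct": ct.ra950_pct, "ra910_pct": ct.ra910_pct,
                        "ra856_pct": ct.ra856_pct, "hu15_hu": ct.hu15_hu,
                        "ct_emphysema": ct.emphysema})

    pd.DataFrame([metrics]).to_csv(out / "metrics.csv", index=False)
    (out / "report.txt").write_text(
        "\n".join(["file analysis", "============="]
                  + [f"{k}: {v}" for k, v in metrics.items()]) + "\n"
    )
    return metrics
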