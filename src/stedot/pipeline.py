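"""End-to-end orchestration: volumes + protocol -> debias -> fits -> report.

``run_analysis`` executes the full estimation chain on aligned 4-D volumes,
an acquisition protocol and an ROI label map; ``run_simulation`` wraps the
synthetic generator with on-disk output.  Both are deterministic given their
seeds, and every configuration value is recorded verbatim in the run
manifest.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .btensor import (
    AcquisitionProtocol,
    GradientWaveform,
    S_MM2_PER_MS_UM2,
    load_protocol,
    save_protocol,
)
from .fit import (
    DEFAULT_BS,
    estimate_s0_lowb,
    fdot_upper_limit,
    fit_highb_monoexp,
    fit_highb_t2,
    fit_sphere_radius,
    roi_summary,
    shell_average,
)
from .noise import debias_rician, estimate_sigma_background, noise_floor, snr_tsnr
from .simulate import SyntheticDataset, generate, make_preset, ste_protocol

__all__ = ["PipelineConfig", "AnalysisResult", "run_analysis", "run_simulation"]

_MAP_NAMES = ("fdot", "f1", "d1", "s0", "t2", "r_s", "snr", "tsnr")


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of one analysis run; everything lands in the manifest."""

    bs: float = DEFAULT_BS  # ms/um^2; shells with b > bs enter the fits
    n_starts: int = 10
    seed: int = 0
    debias: bool = True
    s0_method: str = "loglinear_two_lowest"
    sigma: float | None = None  # known noise level; estimated from background if None
    fit_t2: str = "auto"  # "auto" | "never"
    fit_sphere: bool = False
    sphere_d_s: float = 3.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class AnalysisResult:
    maps: dict[str, np.ndarray]
    roi_table: pd.DataFrame
    voxel_table: pd.DataFrame
    manifest: dict


def _voxel_fit(
    signal: np.ndarray,
    protocol: AcquisitionProtocol,
    config: PipelineConfig,
    sigma: float,
    waveform: GradientWaveform | None,
) -> dict:
    """Run the estimation chain for one voxel; returns a result row."""
    shells = shell_average(signal, protocol)
    te_min = shells["te"].min()
    low_te = shells[shells["te"] == te_min].reset_index(drop=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        s0 = estimate_s0_lowb(low_te)
    row: dict = {"s0": s0}
    if s0 > 0.0:
        row["fdot_pct"] = 100.0 * fdot_upper_limit(low_te, s0)
        row["rel_floor_pct"] = 100.0 * noise_floor(sigma) / s0
    else:
        row["fdot_pct"] = math.nan
        row["rel_floor_pct"] = math.nan
        row["flags"] = "s0_nonpositive"
        return row

    fit = fit_highb_monoexp(
        low_te, s0, bs=config.bs, n_starts=config.n_starts, seed=config.seed
    )
    row["f1_pct"] = 100.0 * fit.f1_tilde
    row["d1"] = fit.d1_tilde
    flags = list(fit.flags)

    n_tes = shells["te"].nunique()
    if config.fit_t2 == "auto" and n_tes >= 3:
        t2fit = fit_highb_t2(
            shells, s0, bs=config.bs, n_starts=config.n_starts, seed=config.seed
        )
        row["t2"] = t2fit.t2_1
        flags += [f for f in t2fit.flags if f not in flags]
    if config.fit_sphere and waveform is not None:
        sfit = fit_sphere_radius(
            low_te,
            waveform,
            s0,
            bs=config.bs,
            d_s=config.sphere_d_s,
            n_starts=config.n_starts,
            seed=config.seed,
        )
        row["r_s"] = sfit.r_s
        flags += [f for f in sfit.flags if f not in flags]
    if flags:
        row["flags"] = ";".join(flags)
    return row


def run_analysis(
    volumes,
    protocol: AcquisitionProtocol,
    rois,
    config: PipelineConfig = PipelineConfig(),
    waveform: GradientWaveform | None = None,
    roi_names: dict[int, str] | None = None,
    outdir=None,
) -> AnalysisResult:
    """Debias, shell-average and fit every ROI voxel; summarise per ROI.

    ``volumes`` is a 4-D array aligned to ``protocol`` along its last axis;
    ``rois`` an integer label volume (0 = background).  The noise sigma is
    taken from the config or estimated from background voxels.  Requires at
    least two shells above the high-b cut-off.
    """
    volumes = np.asarray(volumes, dtype=float)
    rois = np.asarray(rois)
    if volumes.shape[-1] != len(protocol):
        raise ValueError(
            f"volume count {volumes.shape[-1]} does not match protocol length {len(protocol)}"
        )
    if rois.shape != volumes.shape[:-1]:
        raise ValueError("ROI volume shape does not match the data grid")
    n_high = np.unique(protocol.b[protocol.b > config.bs]).size
    if n_high < 2:
        raise ValueError(
            f"protocol has {n_high} shells above bs = {config.bs} ms/um^2; need >= 2"
        )

    if config.sigma is not None:
        sigma = float(config.sigma)
    else:
        sigma = estimate_sigma_background(volumes, rois == 0)

    data = debias_rician(volumes, sigma) if (config.debias and sigma > 0) else volumes

    b0_series = data[..., protocol.is_b0]
    snr_map, tsnr_map = snr_tsnr(b0_series.reshape(-1, b0_series.shape[-1]), sigma)
    snr_map = snr_map.reshape(rois.shape)
    tsnr_map = tsnr_map.reshape(rois.shape)

    rows = []
    for idx in np.argwhere(rois > 0):
        idx = tuple(idx)
        row = _voxel_fit(data[idx], protocol, config, sigma, waveform)
        label = int(rois[idx])
        row["roi"] = roi_names.get(label, str(label)) if roi_names else str(label)
        row["index"] = idx
        row["snr"] = float(snr_map[idx])
        row["tsnr"] = float(tsnr_map[idx])
        rows.append(row)
    voxel_table = pd.DataFrame(rows)

    roi_table = roi_summary(voxel_table)

    maps = {"snr": snr_map, "tsnr": tsnr_map}
    for name, col in (
        ("fdot", "fdot_pct"),
        ("f1", "f1_pct"),
        ("d1", "d1"),
        ("s0", "s0"),
        ("t2", "t2"),
        ("r_s", "r_s"),
    ):
        if col not in voxel_table:
            continue
        vol = np.full(rois.shape, np.nan)
        for _, r in voxel_table.iterrows():
            vol[r["index"]] = r[col]
        maps[name] = vol

    manifest = {
        "software": {"name": "stedot", "version": __version__},
        "config": config.to_dict(),
        "sigma": sigma,
        "n_voxels_fitted": int(len(voxel_table)),
        "n_volumes": int(volumes.shape[-1]),
        "shells_s_mm2": [float(s * S_MM2_PER_MS_UM2) for s in protocol.shells],
        "tes_ms": [float(t) for t in protocol.tes],
    }

    result = AnalysisResult(maps, roi_table, voxel_table, manifest)
    if outdir is not None:
        _write_analysis(result, Path(outdir))
    return result


def _affine() -> np.ndarray:
    # 4 mm isotropic grid, scanner-anonymous orientation
    return np.diag([4.0, 4.0, 4.0, 1.0])


def _write_analysis(result: AnalysisResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for name, vol in result.maps.items():
        nib.save(nib.Nifti1Image(vol.astype(np.float64), _affine()), outdir / f"{name}.nii")
    result.roi_table.to_csv(outdir / "roi_table.tsv", sep="\t", index=False)
    result.voxel_table.drop(columns=["index"], errors="ignore").to_csv(
        outdir / "voxel_table.tsv", sep="\t", index=False
    )
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(result.manifest, fh, sort_keys=False)


def run_simulation(
    preset_name: str,
    tes=(88.0,),
    grid_shape=(5, 5, 8),
    seed: int = 0,
    outdir=None,
    **preset_overrides,
) -> SyntheticDataset:
    """Generate a synthetic dataset for a named preset; optionally save it.

    On-disk layout: ``volumes.nii`` and ``roi_labels.nii``, the protocol
    table, the truth table (TSV) and a manifest recording the preset, every
    default and the seed.
    """
    preset = make_preset(preset_name, **preset_overrides)
    protocol = ste_protocol(tes)
    dataset = generate(preset, protocol, grid_shape=grid_shape, seed=seed)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        nib.save(
            nib.Nifti1Image(dataset.volumes.astype(np.float64), _affine()),
            outdir / "volumes.nii",
        )
        nib.save(
            nib.Nifti1Image(dataset.roi_labels.astype(np.int16), _affine()),
            outdir / "roi_labels.nii",
        )
        save_protocol(dataset.protocol, outdir / "protocol.txt")
        dataset.truth.to_csv(outdir / "truth.tsv", sep="\t")
        manifest = {
            "software": {"name": "stedot", "version": __version__},
            "preset": {
                "name": preset.name,
                "snr_b0": preset.snr_b0,
                "voxelwise_jitter": preset.voxelwise_jitter,
                "compartments": [
                    {
                        "kind": c.kind,
                        "fraction": c.fraction,
                        "d_par": c.d_par,
                        "d_perp": c.d_perp,
                        "od": c.od,
                        "t2": c.t2,
                    }
                    for c in preset.model.compartments
                ],
            },
            "tes_ms": [float(t) for t in tes],
            "grid_shape": list(dataset.roi_labels.shape),
            "seed": int(seed),
            "sigma": float(dataset.sigma),
        }
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
    return dataset


def load_dataset_dir(path) -> tuple[np.ndarray, AcquisitionProtocol, np.ndarray, dict]:
    """Read back a dataset written by :func:`run_simulation`."""
    path = Path(path)
    volumes = np.asarray(nib.load(path / "volumes.nii").dataobj, dtype=float)
    rois = np.asarray(nib.load(path / "roi_labels.nii").dataobj).astype(int)
    protocol = load_protocol(path / "protocol.txt")
    with open(path / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    return volumes, protocol, rois, manifest
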