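"""Reading and writing the pipeline's file formats.

Images travel as 8- or 16-bit greyscale PNG/TIFF frames listed in a CSV
manifest (``file, sample_id, blend_label, time_h``, plus optional well
geometry columns); spectra as two-column ``ppm, intensity`` CSV with their
own manifest (``file, time_h``).  All tabular outputs are plain CSV and all
run metadata is JSON, so every artifact stays diffable.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import __version__
from .images import BinarySeries, ImageSeries, ThresholdRange, circular_mask, to_grey
from .kinetics import KineticCurve, T50Fit
from .nmr import Spectrum
from .stats import GroupComparison

__all__ = [
    "write_image_series",
    "read_image_series",
    "write_masks",
    "write_kinetics",
    "read_kinetics",
    "write_threshold_json",
    "write_t50_table",
    "read_t50_table",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "read_spectra_manifest",
    "write_group_comparison",
]

MANIFEST_COLUMNS = ["file", "sample_id", "blend_label", "time_h"]
_WELL_COLUMNS = ["well_center_y", "well_center_x", "well_radius"]


def write_image_series(
    series: ImageSeries,
    outdir: str | Path,
    bit_depth: int = 8,
    fmt: str = "png",
) -> pd.DataFrame:
    """Write a series' frames and return its manifest rows.

    Frames are quantized to the requested bit depth.  Well geometry, when
    the series carries a circular mask's bounding parameters, is not
    re-derived from the mask; callers that need it in the manifest should
    add the ``well_center_y/x`` and ``well_radius`` columns themselves (the
    convenience wrappers in :mod:`phbdeg.workflow` do).
    """
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dtype, scale = (np.uint8, 255) if bit_depth == 8 else (np.uint16, 65535)
    rows = []
    for frame, t in zip(series.frames, series.times):
        name = f"{series.sample_id or 'series'}_t{t:07.1f}h.{fmt}"
        iio.imwrite(outdir / name, (np.clip(frame, 0, 1) * scale + 0.5).astype(dtype))
        rows.append(
            {
                "file": name,
                "sample_id": series.sample_id,
                "blend_label": series.blend_label,
                "time_h": float(t),
            }
        )
    return pd.DataFrame(rows)


def read_image_series(manifest_path: str | Path, images_root: str | Path | None = None) -> list[ImageSeries]:
    """Load every sample's series from a manifest CSV.

    Frames are converted to grey [0, 1] on load.  If the manifest carries
    ``well_center_y``, ``well_center_x`` and ``well_radius`` columns, a
    circular well mask is attached to each series.
    """
    manifest_path = Path(manifest_path)
    root = Path(images_root) if images_root is not None else manifest_path.parent
    df = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    out = []
    for sample_id, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("time_h")
        frames = [to_grey(iio.imread(root / f)) for f in grp["file"]]
        mask = None
        if all(c in grp.columns for c in _WELL_COLUMNS):
            r0 = grp.iloc[0]
            mask = circular_mask(
                frames[0].shape, (r0["well_center_y"], r0["well_center_x"]), r0["well_radius"]
            )
        out.append(
            ImageSeries(
                frames=frames,
                times=grp["time_h"].to_numpy(),
                sample_id=str(sample_id),
                blend_label=str(grp["blend_label"].iloc[0]),
                well_mask=mask,
            )
        )
    return out


def write_masks(binary: BinarySeries, outdir: str | Path) -> list[Path]:
    """Write each boolean mask as a 0/255 PNG."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for mask, t in zip(binary.masks, binary.times):
        p = outdir / f"{binary.sample_id or 'series'}_t{t:07.1f}h_mask.png"
        iio.imwrite(p, (mask.astype(np.uint8) * 255))
        paths.append(p)
    return paths


def write_kinetics(entries: list[tuple[BinarySeries, KineticCurve]], path: str | Path) -> None:
    """Tidy kinetics CSV: one row per (sample, time point)."""
    rows = []
    for binary, curve in entries:
        for t, wp, val in zip(curve.times, binary.white_counts, curve.values):
            rows.append(
                {
                    "sample_id": curve.sample_id,
                    "blend_label": curve.blend_label,
                    "time_h": float(t),
                    "wp_count": int(wp),
                    "remaining_pct": float(val),
                }
            )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_kinetics(path: str | Path) -> list[KineticCurve]:
    df = pd.read_csv(path)
    curves = []
    for sample_id, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("time_h")
        curves.append(
            KineticCurve(
                times=grp["time_h"].to_numpy(),
                values=grp["remaining_pct"].to_numpy(),
                sample_id=str(sample_id),
                blend_label=str(grp["blend_label"].iloc[0]),
            )
        )
    return curves


def write_threshold_json(thr: ThresholdRange, path: str | Path, **metadata) -> None:
    """Record the threshold range (and any run metadata) beside the masks."""
    payload = {"low": thr.low, "high": thr.high, "phbdeg_version": __version__, **metadata}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def write_t50_table(fits: list[tuple[str, str, int, T50Fit]], path: str | Path) -> None:
    """Tidy t50 CSV: one row per (sample_id, blend_label, replicate)."""
    rows = [
        {
            "sample_id": sid,
            "blend_label": blend,
            "replicate": rep,
            "t50_h": np.nan if fit.t50 is None else fit.t50,
            "censored": fit.censored or "",
            "degree": fit.degree,
            "r2": fit.r2,
            "adj_r2": fit.adj_r2,
            "f_pvalue": fit.f_pvalue,
        }
        for sid, blend, rep, fit in fits
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_t50_table(path: str | Path) -> dict[str, np.ndarray]:
    """t50 values grouped by blend; censored entries come back as NaN."""
    df = pd.read_csv(path)
    return {
        str(blend): grp["t50_h"].to_numpy(dtype=float)
        for blend, grp in df.groupby("blend_label", sort=False)
    }


def write_spectrum_csv(spec: Spectrum, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"ppm": spec.ppm, "intensity": spec.intensity}).to_csv(path, index=False)


def read_spectrum_csv(path: str | Path, time_h: float | None = None, label: str = "") -> Spectrum:
    df = pd.read_csv(path)
    if not {"ppm", "intensity"} <= set(df.columns):
        raise ValueError("spectrum CSV needs 'ppm' and 'intensity' columns")
    return Spectrum(
        ppm=df["ppm"].to_numpy(), intensity=df["intensity"].to_numpy(), time_h=time_h, label=label
    )


def read_spectra_manifest(manifest_path: str | Path, root: str | Path | None = None) -> list[Spectrum]:
    """Load a time series of spectra from a (file, time_h) manifest CSV."""
    manifest_path = Path(manifest_path)
    root = Path(root) if root is not None else manifest_path.parent
    df = pd.read_csv(manifest_path)
    if not {"file", "time_h"} <= set(df.columns):
        raise ValueError("spectra manifest needs 'file' and 'time_h' columns")
    return [
        read_spectrum_csv(root / r["file"], time_h=float(r["time_h"]), label=str(r["file"]))
        for _, r in df.sort_values("time_h").iterrows()
    ]


def write_group_comparison(gc: GroupComparison, outdir: str | Path, prefix: str = "t50") -> None:
    """ANOVA table, Tukey pairs and letter display as three CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "anova_F": gc.anova_F,
                "anova_p": gc.anova_p,
                "k_groups": len(gc.groups),
                "n_total": int(sum(v.size for v in gc.group_values.values())),
                "alpha": gc.alpha,
            }
        ]
    ).to_csv(outdir / f"{prefix}_anova.csv", index=False)
    pd.DataFrame(
        [
            {
                "group_a": p.group_a,
                "group_b": p.group_b,
                "difference": p.difference,
                "q_statistic": p.q_statistic,
                "p_value": p.p_value,
                "reject": p.reject,
            }
            for p in gc.tukey_pairs
        ]
    ).to_csv(outdir / f"{prefix}_tukey.csv", index=False)
    pd.DataFrame(
        [
            {
                "blend_label": g,
                "mean": float(gc.group_values[g].mean()),
                "n": int(gc.group_values[g].size),
                "letters": gc.letters[g],
            }
            for g in gc.groups
        ]
    ).to_csv(outdir / f"{prefix}_letters.csv", index=False)
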