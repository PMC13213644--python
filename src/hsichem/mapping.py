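"""Pixel-wise concentration prediction and pseudo-color rendering.

Every foreground pixel's reflectance spectrum is pushed through a trained
calibration model (pre-processing chain, band subset and learner replayed
exactly as in training), producing a per-pixel concentration grid.  The grid
renders with a red-to-black palette — red for high concentration, black for
low — and background pixels render black.  Negative predictions are rendered
at the black endpoint but written to CSV unmodified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .hsi_io import ReflectanceCube
from .models import TrainedPredictor

__all__ = ["ConcentrationMap", "predict_pixel_map", "render_map"]


@dataclass
class ConcentrationMap:
    """Per-pixel predicted analyte level; background pixels are NaN."""

    values: np.ndarray                 # (rows, cols); NaN on background
    mask: np.ndarray                   # True = foreground
    analyte: str = ""
    units: str = "mg/g"

    @property
    def foreground_values(self) -> np.ndarray:
        return self.values[self.mask]

    def bounds(self) -> tuple[float, float]:
        v = self.foreground_values
        return float(np.nanmin(v)), float(np.nanmax(v))

    def to_csv(self, path) -> None:
        np.savetxt(path, self.values, delimiter=",", fmt="%.6g")


def predict_pixel_map(
    cube: ReflectanceCube,
    model: TrainedPredictor,
    mask: np.ndarray,
    analyte: str = "",
) -> ConcentrationMap:
    """Apply a trained regression model to every foreground pixel."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise ValueError("mask shape must match the pixel grid")
    if not mask.any():
        raise ValueError("mask marks no foreground pixels")
    if model.wavelengths is not None and not np.array_equal(
        model.wavelengths, cube.wavelengths
    ):
        raise ValueError("cube band axis does not match the model's stored axis")
    spectra = cube.data[mask]
    preds = np.asarray(model.predict(spectra), dtype=float).ravel()
    if not np.all(np.isfinite(preds)):
        raise ValueError("model produced non-finite pixel predictions")
    values = np.full(mask.shape, np.nan)
    values[mask] = preds
    return ConcentrationMap(values=values, mask=mask, analyte=analyte)


def _red_black_rgb(norm: np.ndarray) -> np.ndarray:
    """Map [0, 1] to black -> red; NaN maps to black."""
    v = np.nan_to_num(np.clip(norm, 0.0, 1.0), nan=0.0)
    rgb = np.zeros(v.shape + (3,), dtype=np.uint8)
    rgb[..., 0] = np.round(v * 255).astype(np.uint8)
    return rgb


def render_map(
    cmap: ConcentrationMap,
    path,
    bounds: tuple[float, float] | None = None,
    colorbar: bool = True,
) -> Path:
    """Render the concentration grid to a PNG (deterministic byte-for-byte).

    ``bounds`` defaults to the foreground min/max; a degenerate scale
    (min == max) renders a single color and emits a warning.  With
    ``colorbar=True`` an annotated companion figure ``<path>_colorbar.png``
    is written as well.
    """
    from PIL import Image

    path = Path(path)
    lo, hi = bounds if bounds is not None else cmap.bounds()
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise ValueError("color-scale bounds must be finite")
    if hi == lo:
        warnings.warn("degenerate color scale (min == max): single-color render")
        norm = np.where(cmap.mask, 1.0, np.nan)
    else:
        norm = (cmap.values - lo) / (hi - lo)
        norm = np.where(cmap.mask, norm, np.nan)
    Image.fromarray(_red_black_rgb(norm), mode="RGB").save(path)

    if colorbar:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import LinearSegmentedColormap, Normalize

        pal = LinearSegmentedColormap.from_list("redblack", ["black", "red"])
        fig, ax = plt.subplots(figsize=(1.4, 4))
        fig.colorbar(
            plt.cm.ScalarMappable(norm=Normalize(lo, hi if hi > lo else lo + 1),
                                  cmap=pal),
            cax=ax,
            label=f"{cmap.analyte} ({cmap.units})".strip(),
        )
        fig.savefig(path.with_name(path.stem + "_colorbar.png"),
                    dpi=120, bbox_inches="tight")
        plt.close(fig)
    return path
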