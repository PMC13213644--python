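"""Spectral pre-processing: SNV, Savitzky-Golay smoothing and SG derivatives.

The named chains mirror the treatments compared in the study: Raw, SG, SNV,
1stD, 2ndD, 1stD-SG, 2ndD-SG (hyphenated names read left to right — the
derivative is taken first, then smoothed), plus the SNV combinations
SNV-SG / SNV-1stD / SNV-2ndD.

Derivatives are Savitzky-Golay derivative filters (local polynomial fits, not
finite differences) in units of reflectance per band index.  Edge samples are
handled by polynomial fits on the boundary windows (scipy's ``interp`` mode).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "PreprocessChain",
    "snv",
    "sg_filter",
    "apply_chain",
    "chain_from_name",
    "CHAIN_NAMES",
    "DEFAULT_WINDOW",
    "DEFAULT_POLYORDER",
]

DEFAULT_WINDOW = 11
DEFAULT_POLYORDER = 3

# step := ("snv",) | ("sg", window, polyorder, deriv)
Step = tuple


def snv(spectra: np.ndarray) -> np.ndarray:
    """Standard normal variate: center and scale each spectrum (row) to unit
    sample SD (n-1 denominator).  Removes multiplicative and additive scatter.

    Raises ``ValueError`` identifying the first constant row.
    """
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    if x.shape[1] < 2:
        raise ValueError("SNV needs spectra with at least 2 bands")
    sd = x.std(axis=1, ddof=1)
    flat = np.where(sd == 0)[0]
    if flat.size:
        raise ValueError(f"constant spectrum at row {flat[0]}: SNV undefined")
    out = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return out if np.asarray(spectra).ndim == 2 else out[0]


def sg_filter(
    spectra: np.ndarray,
    window: int = DEFAULT_WINDOW,
    polyorder: int = DEFAULT_POLYORDER,
    deriv: int = 0,
) -> np.ndarray:
    """Savitzky-Golay smoothing (deriv=0) or derivative (deriv=1, 2) per row."""
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if not 0 <= deriv <= 2 or polyorder < deriv:
        raise ValueError("deriv must be in {0,1,2} and <= polyorder")
    x = np.asarray(spectra, dtype=float)
    if x.shape[-1] < window:
        raise ValueError("spectrum shorter than the filter window")
    return savgol_filter(x, window, polyorder, deriv=deriv, axis=-1, mode="interp")


@dataclass(frozen=True)
class PreprocessChain:
    """Ordered pre-processing steps applied left to right."""

    name: str
    steps: tuple[Step, ...]

    def __call__(self, spectra: np.ndarray) -> np.ndarray:
        return apply_chain(spectra, self)


def apply_chain(spectra: np.ndarray, chain: PreprocessChain) -> np.ndarray:
    x = np.asarray(spectra, dtype=float)
    for step in chain.steps:
        kind = step[0]
        if kind == "snv":
            x = snv(x)
        elif kind == "sg":
            _, window, polyorder, deriv = step
            x = sg_filter(x, window, polyorder, deriv)
        else:
            raise ValueError(f"unknown pre-processing step {kind!r}")
    return x


def _named_steps(name: str, window: int, polyorder: int) -> tuple[Step, ...]:
    sg = ("sg", window, polyorder, 0)
    d1 = ("sg", window, polyorder, 1)
    d2 = ("sg", window, polyorder, 2)
    table = {
        "raw": (),
        "sg": (sg,),
        "snv": (("snv",),),
        "1std": (d1,),
        "2ndd": (d2,),
        "1std-sg": (d1, sg),
        "2ndd-sg": (d2, sg),
        "snv-sg": (("snv",), sg),
        "snv-1std": (("snv",), d1),
        "snv-2ndd": (("snv",), d2),
    }
    key = name.lower()
    if key not in table:
        raise ValueError(f"unknown chain name {name!r}; known: {sorted(table)}")
    return table[key]


def chain_from_name(
    name: str, window: int = DEFAULT_WINDOW, polyorder: int = DEFAULT_POLYORDER
) -> PreprocessChain:
    """Build a named chain, e.g. ``"2ndD-SG"`` (derivative, then smoothing)."""
    return PreprocessChain(name=name, steps=_named_steps(name, window, polyorder))


CHAIN_NAMES = ("Raw", "SG", "SNV", "1stD", "2ndD", "1stD-SG", "2ndD-SG")
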