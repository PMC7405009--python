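"""Spectral pre-processing operators and the seven ordered pipelines.

The operators are the chemometric staples for diffuse-reflectance NIR of
powders: region cutting, moving-average smoothing, multiplicative scatter
correction (MSC), standard normal variate (SNV), finite-difference
derivatives, polynomial detrending, wavenumber binning and replicate
averaging.  Seven named approaches ("i"–"vii") combine them in fixed order;
all end with a 10-point binning followed by triplicate averaging.

Order matters: the high-wavenumber region (> 9000 cm^-1) carries large,
sample-specific offsets, so it must be cut *before* MSC — otherwise the
offset variance leaks through the scatter-correction fit into the retained
region.  ``PipelineSpec`` enforces that ordering unless explicitly
overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .spectra_io import SpectraSet

STEP_KINDS = (
    "cut",
    "smooth",
    "msc",
    "derivative",
    "detrend",
    "snv",
    "bin",
    "average_replicates",
)

#: Table of named approaches: ordered (kind, params) before the terminal
#: bin + replicate-average steps shared by all of them.
_APPROACHES = {
    "i": [("cut", {"threshold": 9000.0}), ("msc", {})],
    "ii": [("cut", {"threshold": 9000.0}), ("msc", {}), ("derivative", {"order": 1})],
    "iii": [("cut", {"threshold": 9000.0}), ("msc", {}), ("derivative", {"order": 2})],
    "iv": [("cut", {"threshold": 9000.0}), ("msc", {}), ("detrend", {"poly_order": 1})],
    "v": [
        ("cut", {"threshold": 9000.0}),
        ("smooth", {"span": 5}),
        ("msc", {}),
        ("derivative", {"order": 1}),
    ],
    "vi": [
        ("cut", {"threshold": 6000.0}),
        ("smooth", {"span": 5}),
        ("msc", {}),
        ("derivative", {"order": 2}),
    ],
    "vii": [
        ("cut", {"threshold": 9000.0}),
        ("smooth", {"span": 5}),
        ("msc", {}),
        ("detrend", {"poly_order": 1}),
    ],
}

APPROACH_IDS = tuple(_APPROACHES)


@dataclass
class Step:
    kind: str
    params: dict = field(default_factory=dict)


@dataclass
class PipelineSpec:
    """An ordered list of pre-processing steps.

    Invariants enforced on construction: each step kind appears at most
    once; ``cut`` precedes ``msc`` (set ``allow_unsafe_order=True`` to
    study the wrong order deliberately); ``bin`` and then
    ``average_replicates`` are terminal when present.
    """

    steps: list
    allow_unsafe_order: bool = False

    def __post_init__(self):
        self.steps = [s if isinstance(s, Step) else Step(*s) for s in self.steps]
        kinds = [s.kind for s in self.steps]
        for k in kinds:
            if k not in STEP_KINDS:
                raise ValueError(f"unknown step kind '{k}'")
        seen = [k for k in set(kinds) if kinds.count(k) > 1]
        if seen:
            raise ValueError(f"step kinds repeated: {sorted(seen)}")
        if "cut" in kinds and "msc" in kinds and not self.allow_unsafe_order:
            if kinds.index("msc") < kinds.index("cut"):
                raise ValueError(
                    "msc before cut: scatter correction fitted on the full axis "
                    "propagates high-wavenumber offset variance into the "
                    "retained region; reorder to cut->msc or set "
                    "allow_unsafe_order=True"
                )
        for terminal in ("bin", "average_replicates"):
            if terminal in kinds:
                after = kinds[kinds.index(terminal) + 1 :]
                allowed = {"average_replicates"} if terminal == "bin" else set()
                if set(after) - allowed:
                    raise ValueError(
                        f"'{terminal}' must be terminal (followed only by "
                        f"{sorted(allowed) or 'nothing'}), got {after}"
                    )


@dataclass
class MSCFit:
    """Per-spectrum affine fits x_i ~ a_i + b_i * reference."""

    reference: np.ndarray
    intercepts: np.ndarray
    slopes: np.ndarray


def cut_region(s: SpectraSet, threshold: float) -> SpectraSet:
    """Retain only wavenumbers <= ``threshold`` (cm^-1)."""
    keep = s.wavenumbers <= threshold
    if not keep.any():
        raise ValueError(
            f"threshold {threshold} cm^-1 is below the axis minimum "
            f"{s.wavenumbers[0]}; nothing retained"
        )
    return s.with_absorbance(s.absorbance[:, keep], s.wavenumbers[keep])


def smooth_moving_average(s: SpectraSet, span: int = 5) -> SpectraSet:
    """Centred moving average; windows truncate at the edges.

    ``span`` must be odd so the window is symmetric around each point.
    """
    span = int(span)
    if span % 2 == 0:
        raise ValueError(f"span must be odd, got {span}")
    if span < 3 or span > s.n_points:
        raise ValueError(f"span must be in [3, {s.n_points}], got {span}")
    kernel = np.ones(span)
    counts = np.convolve(np.ones(s.n_points), kernel, mode="same")
    sums = np.apply_along_axis(
        lambda row: np.convolve(row, kernel, mode="same"), 1, s.absorbance
    )
    return s.with_absorbance(sums / counts)


def msc(s: SpectraSet, reference="mean") -> tuple[SpectraSet, MSCFit]:
    """Multiplicative scatter correction against a reference spectrum.

    Each row is regressed on the reference by ordinary least squares,
    ``x_i ~ a_i + b_i * r``, and corrected to ``(x_i - a_i) / b_i``.  With
    ``reference="mean"`` the reference is the mean spectrum of the rows
    being corrected, i.e. of the current working subset — subset analyses
    therefore use a subset-scoped reference automatically.
    """
    if s.n_spectra < 1:
        raise ValueError("msc needs at least one spectrum")
    r = s.absorbance.mean(axis=0) if isinstance(reference, str) else np.asarray(reference, float)
    if r.size != s.n_points:
        raise ValueError("reference length does not match the axis")
    r_centered = r - r.mean()
    denom = r_centered @ r_centered
    if denom < 1e-12 * r.size:
        raise ValueError("degenerate reference spectrum (zero variance)")
    x = s.absorbance
    slopes = (x - x.mean(axis=1, keepdims=True)) @ r_centered / denom
    bad = np.flatnonzero(np.abs(slopes) < 1e-12)
    if bad.size:
        raise ValueError(f"near-zero MSC slope for row(s) {bad.tolist()}")
    intercepts = x.mean(axis=1) - slopes * r.mean()
    corrected = (x - intercepts[:, None]) / slopes[:, None]
    return s.with_absorbance(corrected), MSCFit(r, intercepts, slopes)


def snv(s: SpectraSet) -> SpectraSet:
    """Standard normal variate: centre and unit-scale each row."""
    sd = s.absorbance.std(axis=1, ddof=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance row(s) {bad.tolist()} cannot be SNV-scaled")
    out = (s.absorbance - s.absorbance.mean(axis=1, keepdims=True)) / sd[:, None]
    return s.with_absorbance(out)


def _check_equal_spacing(w: np.ndarray) -> float:
    d = np.diff(w)
    h = d.mean()
    if np.max(np.abs(d - h)) > 1e-6 * abs(h):
        raise ValueError("derivative requires an equally spaced axis")
    return h


def derivative(s: SpectraSet, order: int = 1, savitzky_golay: bool = False,
               window: int = 7, polyorder: int = 2) -> SpectraSet:
    """d/dnu or d2/dnu2 by finite differences on the wavenumber axis.

    Default is the plain stencil: central differences in the interior,
    one-sided at the edges (first order), and the 3-point second-difference
    stencil (second order).  Set ``savitzky_golay=True`` for a SG derivative
    filter instead.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if s.n_points < order + 1:
        raise ValueError("too few points for the requested derivative order")
    h = _check_equal_spacing(s.wavenumbers)
    if savitzky_golay:
        out = savgol_filter(
            s.absorbance, window_length=window, polyorder=polyorder,
            deriv=order, delta=h, axis=1, mode="interp",
        )
        return s.with_absorbance(out)
    x = s.absorbance
    if order == 1:
        out = np.gradient(x, h, axis=1)
    else:
        out = np.empty_like(x)
        out[:, 1:-1] = (x[:, 2:] - 2 * x[:, 1:-1] + x[:, :-2]) / h**2
        # one-sided: reuse the nearest interior stencil
        out[:, 0] = (x[:, 2] - 2 * x[:, 1] + x[:, 0]) / h**2
        out[:, -1] = (x[:, -1] - 2 * x[:, -2] + x[:, -3]) / h**2
    return s.with_absorbance(out)


def detrend(s: SpectraSet, poly_order: int = 1) -> SpectraSet:
    """Subtract each row's least-squares polynomial in the wavenumber."""
    if poly_order < 0:
        raise ValueError("poly_order must be >= 0")
    if poly_order >= s.n_points:
        raise ValueError(
            f"poly_order {poly_order} >= number of points {s.n_points}"
        )
    # scaled axis keeps the Vandermonde system well conditioned
    w = s.wavenumbers
    span_w = float(np.ptp(w))
    t = (w - w.mean()) / (span_w / 2 if span_w else 1.0)
    basis = np.vander(t, poly_order + 1, increasing=True)
    coeffs, *_ = np.linalg.lstsq(basis, s.absorbance.T, rcond=None)
    return s.with_absorbance(s.absorbance - (basis @ coeffs).T)


def bin_mean(s: SpectraSet, width: int = 10) -> SpectraSet:
    """Average non-overlapping blocks of ``width`` adjacent wavenumbers.

    The axis is block-averaged the same way; a trailing incomplete block is
    dropped.
    """
    width = int(width)
    if width < 1:
        raise ValueError("width must be >= 1")
    if width > s.n_points:
        raise ValueError(f"width {width} exceeds {s.n_points} points")
    nb = s.n_points // width
    trimmed = s.absorbance[:, : nb * width]
    new_axis = s.wavenumbers[: nb * width].reshape(nb, width).mean(axis=1)
    binned = trimmed.reshape(s.n_spectra, nb, width).mean(axis=2)
    return s.with_absorbance(binned, new_axis)


def average_replicates(s: SpectraSet) -> SpectraSet:
    """Collapse replicate spectra to one mean spectrum per sample."""
    if not s.has_replicates:
        raise ValueError("no replicate column in metadata; already averaged?")
    meta = s.meta
    for sid, grp in meta.groupby("sample_id", sort=False):
        if grp["species"].nunique() > 1:
            raise ValueError(
                f"sample '{sid}' carries inconsistent species labels: "
                f"{sorted(grp['species'].unique())}"
            )
    order = meta["sample_id"].drop_duplicates().tolist()
    rows, recs = [], []
    for sid in order:
        idx = np.flatnonzero((meta["sample_id"] == sid).to_numpy())
        rows.append(s.absorbance[idx].mean(axis=0))
        rec = meta.iloc[idx[0]].drop(labels="replicate")
        recs.append(rec)
    new_meta = pd.DataFrame(recs).reset_index(drop=True)
    return SpectraSet(
        wavenumbers=s.wavenumbers,
        absorbance=np.vstack(rows),
        meta=new_meta,
        provenance=list(s.provenance),
    )


_DISPATCH = {
    "cut": lambda s, p: cut_region(s, **p),
    "smooth": lambda s, p: smooth_moving_average(s, **p),
    "msc": lambda s, p: msc(s, **p)[0],
    "snv": lambda s, p: snv(s, **p),
    "derivative": lambda s, p: derivative(s, **p),
    "detrend": lambda s, p: detrend(s, **p),
    "bin": lambda s, p: bin_mean(s, **p),
    "average_replicates": lambda s, p: average_replicates(s, **p),
}


def apply_pipeline(s: SpectraSet, p: PipelineSpec) -> SpectraSet:
    """Apply the steps of ``p`` strictly in order, logging provenance."""
    out = s
    for step in p.steps:
        out = _DISPATCH[step.kind](out, step.params)
        out.provenance.append(
            {
                "step": step.kind,
                "params": dict(step.params),
                "shape": [out.n_spectra, out.n_points],
            }
        )
    return out


def make_approach(approach_id: str, bin_width: int = 10,
                  average: bool = True) -> PipelineSpec:
    """Return the named pre-processing pipeline ("i" .. "vii").

    Every approach ends with ``bin(bin_width)`` and (by default) replicate
    averaging.
    """
    if approach_id not in _APPROACHES:
        raise ValueError(
            f"unknown approach '{approach_id}'; valid ids: {', '.join(APPROACH_IDS)}"
        )
    steps = [Step(k, dict(p)) for k, p in _APPROACHES[approach_id]]
    steps.append(Step("bin", {"width": bin_width}))
    if average:
        steps.append(Step("average_replicates", {}))
    return PipelineSpec(steps)
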