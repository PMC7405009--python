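"""Reading and writing FT-NIR spectra and sample metadata as plain CSV tables.

The on-disk convention is two files:

* a spectra table whose first column is ``wavenumber_cm-1`` and whose
  remaining columns hold one replicate spectrum each, named
  ``<sample_id>__r<replicate>`` (or plain ``<sample_id>`` after replicate
  averaging);
* a metadata table with columns
  ``sample_id, species, origin, harvest_year[, replicate]`` — one row per
  spectrum, keyed by ``(sample_id, replicate)``.

A transposed spectra layout (one row per spectrum, wavenumbers as column
headers, first column ``spectrum_id``) is auto-detected on read.

Instruments emit the axis high-to-low; internally the axis is always stored
ascending and absorbance columns are reordered to match.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

WAVENUMBER_COLUMN = "wavenumber_cm-1"
META_COLUMNS = ["sample_id", "species", "origin", "harvest_year", "replicate"]


@dataclass
class SpectraSet:
    """A wavenumber axis, an absorbance matrix and per-row metadata.

    Parameters
    ----------
    wavenumbers : ndarray, shape (p,)
        Strictly monotone axis in cm^-1.  A descending axis is accepted and
        flipped (together with the absorbance columns) on construction.
    absorbance : ndarray, shape (n, p)
        One row per replicate spectrum (or per sample after averaging).
    meta : DataFrame, length n
        Must carry ``sample_id`` and ``species``; ``replicate`` is present
        until replicates are averaged.
    provenance : list of dict
        Processing log: one entry per pipeline step applied.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    meta: pd.DataFrame
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.wavenumbers.ndim != 1:
            raise ValueError("wavenumbers must be one-dimensional")
        d = np.diff(self.wavenumbers)
        if len(d) and np.all(d < 0):  # instrument order: flip to ascending
            self.wavenumbers = self.wavenumbers[::-1].copy()
            self.absorbance = self.absorbance[:, ::-1].copy()
        elif len(d) and not np.all(d > 0):
            raise ValueError("wavenumber axis must be strictly monotone")
        if self.absorbance.shape[1] != self.wavenumbers.size:
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} columns but the "
                f"axis has {self.wavenumbers.size} points"
            )
        self.meta = self.meta.reset_index(drop=True)
        if len(self.meta) != self.absorbance.shape[0]:
            raise ValueError(
                f"{len(self.meta)} metadata rows for "
                f"{self.absorbance.shape[0]} spectra"
            )

    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.wavenumbers.size

    @property
    def has_replicates(self) -> bool:
        return "replicate" in self.meta.columns

    def with_absorbance(self, absorbance, wavenumbers=None) -> "SpectraSet":
        """Copy of self with a new matrix (and optionally a new axis)."""
        return SpectraSet(
            wavenumbers=self.wavenumbers if wavenumbers is None else wavenumbers,
            absorbance=absorbance,
            meta=self.meta.copy(),
            provenance=list(self.provenance),
        )

    def column_names(self) -> list[str]:
        if self.has_replicates:
            return [
                f"{s}__r{int(r)}"
                for s, r in zip(self.meta["sample_id"], self.meta["replicate"])
            ]
        return list(self.meta["sample_id"].astype(str))


def _spectrum_keys(meta: pd.DataFrame) -> list:
    if "replicate" in meta.columns:
        return [(s, int(r)) for s, r in zip(meta["sample_id"], meta["replicate"])]
    return list(meta["sample_id"])


def _parse_column_name(name: str):
    """Split ``sample__r2`` into ``("sample", 2)``; no suffix means no replicate."""
    if "__r" in name:
        sample_id, rep = name.rsplit("__r", 1)
        return sample_id, int(rep)
    return name, None


def read_spectra(spectra_path, meta_path) -> SpectraSet:
    """Read a spectra CSV and its metadata CSV into a :class:`SpectraSet`.

    Raises ``ValueError`` on orphan keys (spectra without metadata or vice
    versa), duplicate ``(sample_id, replicate)`` keys and non-numeric
    absorbance cells.
    """
    table = pd.read_csv(spectra_path)
    if table.columns[0] == WAVENUMBER_COLUMN:
        wavenumbers = table[WAVENUMBER_COLUMN].to_numpy(dtype=float)
        spec_cols = list(table.columns[1:])
        values = table[spec_cols]
        bad = values.columns[
            [not pd.api.types.is_numeric_dtype(values[c]) for c in values.columns]
        ]
        if len(bad):
            col = bad[0]
            row = values[col][pd.to_numeric(values[col], errors="coerce").isna()].index[0]
            raise ValueError(
                f"non-numeric absorbance in column '{col}', data row {row}"
            )
        absorbance = values.to_numpy(dtype=float).T
        keys = [_parse_column_name(c) for c in spec_cols]
    elif table.columns[0] == "spectrum_id":
        # transposed layout: one row per spectrum, wavenumbers as headers
        wavenumbers = np.array([float(c) for c in table.columns[1:]])
        absorbance = table.iloc[:, 1:].to_numpy(dtype=float)
        keys = [_parse_column_name(str(c)) for c in table["spectrum_id"]]
    else:
        raise ValueError(
            "unrecognised spectra layout: first column must be "
            f"'{WAVENUMBER_COLUMN}' or 'spectrum_id', got '{table.columns[0]}'"
        )

    if any(r is None for _, r in keys):
        keys = [s for s, _ in keys]
    else:
        keys = [(s, r) for s, r in keys]
    dupes = pd.Series(keys)[pd.Series(keys).duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate spectrum keys in spectra file: {dupes}")

    meta = pd.read_csv(meta_path, dtype={"sample_id": str})
    if "origin" in meta.columns:
        meta["origin"] = meta["origin"].fillna("unknown")
    meta_keys = _spectrum_keys(meta)
    meta_dupes = pd.Series(meta_keys)[pd.Series(meta_keys).duplicated()].tolist()
    if meta_dupes:
        raise ValueError(f"duplicate keys in metadata file: {meta_dupes}")

    missing_meta = [k for k in keys if k not in set(meta_keys)]
    missing_spec = [k for k in meta_keys if k not in set(keys)]
    if missing_meta or missing_spec:
        raise ValueError(
            "spectra/metadata mismatch: "
            f"spectra without metadata {missing_meta}; "
            f"metadata without spectra {missing_spec}"
        )
    # align metadata rows to spectra order
    order = pd.Series(range(len(meta_keys)), index=pd.Index(meta_keys))
    meta = meta.iloc[[order[k] for k in keys]].reset_index(drop=True)

    return SpectraSet(wavenumbers=wavenumbers, absorbance=absorbance, meta=meta)


def write_spectra(s: SpectraSet, spectra_path, meta_path) -> None:
    """Write a SpectraSet as the two-CSV convention of :func:`read_spectra`.

    Floats are written in full ``repr`` precision, so a write/read round
    trip reproduces the set to ~1e-16.
    """
    columns = {WAVENUMBER_COLUMN: s.wavenumbers}
    columns.update(zip(s.column_names(), s.absorbance))
    pd.DataFrame(columns).to_csv(spectra_path, index=False)
    meta = s.meta.copy()
    cols = [c for c in META_COLUMNS if c in meta.columns]
    cols += [c for c in meta.columns if c not in cols]
    meta[cols].to_csv(meta_path, index=False)


def make_meta(
    sample_ids, species, origins=None, harvest_years=None, replicates=None
) -> pd.DataFrame:
    """Assemble a metadata frame, defaulting origin to ``"unknown"``."""
    n = len(sample_ids)
    meta = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "species": list(species),
            "origin": ["unknown"] * n if origins is None else list(origins),
            "harvest_year": [pd.NA] * n if harvest_years is None else list(harvest_years),
        }
    )
    if replicates is not None:
        meta["replicate"] = list(replicates)
    return meta
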