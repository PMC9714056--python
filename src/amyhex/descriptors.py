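"""Sequence descriptor engine: 15 families, 4125 features per hexapeptide.

Each family function maps ``(sequence, config, tables)`` to a named numeric
sub-vector; :func:`extract_all` concatenates them in a fixed configurable
order. With the default configuration (lambda=5, nlag=5, window=5) on
length-6 sequences the families contribute

====================  ====
AAINDEX               3186
ZSCALE                  30
EGAAC                   10
DDE                    400
GAAC                     5
GDPC                    25
CTDC                    39
CTDD                   195
PAAC                    25
APAAC                   30
QSOrder                 50
SOCNumber               10
NMBroto                 40
Moran                   40
Geary                   40
====================  ====

for a total of 4125 columns.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .data import LabeledDataset
from .tables import (
    AMINO_ACIDS,
    AUTOCORR_ACCESSIONS,
    CODON_COUNTS,
    CTD_GROUPS,
    GAAC_GROUPS,
    PropertyTableBundle,
    load_tables,
)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

DEFAULT_FAMILY_ORDER = (
    "qsorder", "socnumber", "apaac", "paac", "nmbroto", "geary", "moran",
    "aaindex", "zscale", "egaac", "dde", "gaac", "gdpc", "ctdc", "ctdd",
)


class DescriptorError(ValueError):
    """Invalid sequence or configuration for a descriptor family."""


@dataclass(frozen=True)
class DescriptorConfig:
    """Tunables that fix the descriptor layout.

    Parameters
    ----------
    lam : int
        Sequence-correlation rank for PAAC/APAAC (must be < sequence length).
    w : float
        PAAC/APAAC weight of the correlation block.
    qso_w : float
        QSOrder weight of the coupling-number block.
    nlag : int
        Maximum lag for SOCNumber, QSOrder and the autocorrelations.
    egaac_window : int
        Sliding-window width for EGAAC.
    family_order : tuple of str
        Concatenation order of the 15 families.
    """

    lam: int = 5
    w: float = 0.05
    qso_w: float = 0.1
    nlag: int = 5
    egaac_window: int = 5
    family_order: tuple[str, ...] = DEFAULT_FAMILY_ORDER

    def __post_init__(self):
        if self.lam < 1 or self.nlag < 1 or self.egaac_window < 1:
            raise ValueError("lam, nlag and egaac_window must be >= 1")
        unknown = set(self.family_order) - set(DEFAULT_FAMILY_ORDER)
        if unknown:
            raise ValueError(f"unknown descriptor families: {sorted(unknown)}")

    def dimension(self, length: int = 6, n_aaindex: int = 531) -> int:
        """Total feature count for sequences of the given length."""
        return sum(self.family_dims(length, n_aaindex).values())

    def family_dims(self, length: int = 6, n_aaindex: int = 531) -> dict[str, int]:
        dims = {
            "aaindex": n_aaindex * length,
            "zscale": 5 * length,
            "egaac": (length - self.egaac_window + 1) * 5,
            "dde": 400,
            "gaac": 5,
            "gdpc": 25,
            "ctdc": 39,
            "ctdd": 195,
            "paac": 20 + self.lam,
            "apaac": 20 + 2 * self.lam,
            "qsorder": 2 * (20 + self.nlag),
            "socnumber": 2 * self.nlag,
            "nmbroto": 8 * self.nlag,
            "moran": 8 * self.nlag,
            "geary": 8 * self.nlag,
        }
        return {fam: dims[fam] for fam in self.family_order}


def _check_sequence(seq: str) -> np.ndarray:
    """Validate residues; return integer codes into AMINO_ACIDS order."""
    codes = np.empty(len(seq), dtype=int)
    for pos, aa in enumerate(seq):
        idx = _AA_INDEX.get(aa)
        if idx is None:
            raise DescriptorError(
                f"non-standard residue {aa!r} at position {pos + 1}"
            )
        codes[pos] = idx
    if len(codes) == 0:
        raise DescriptorError("empty sequence")
    return codes


def _require_length(seq: str, minimum: int, what: str) -> None:
    if len(seq) < minimum:
        raise DescriptorError(
            f"{what}: sequence length {len(seq)} < required {minimum}"
        )


# ---------------------------------------------------------------------------
# Composition families

_GAAC_NAMES = tuple(GAAC_GROUPS)
_GAAC_CODE = np.empty(20, dtype=int)
for _g, (_name, _members) in enumerate(GAAC_GROUPS.items()):
    for _aa in _members:
        _GAAC_CODE[_AA_INDEX[_aa]] = _g


def gaac(seq: str, config: DescriptorConfig, tables: PropertyTableBundle):
    """Grouped amino-acid composition over the 5-way partition."""
    codes = _check_sequence(seq)
    counts = np.bincount(_GAAC_CODE[codes], minlength=5)
    names = [f"gaac.{g}" for g in _GAAC_NAMES]
    return names, counts / len(seq)


def egaac(seq: str, config: DescriptorConfig, tables: PropertyTableBundle):
    """Sliding-window GAAC from N- to C-terminus."""
    codes = _check_sequence(seq)
    w = config.egaac_window
    _require_length(seq, w, "egaac")
    names, values = [], []
    for start in range(len(seq) - w + 1):
        counts = np.bincount(_GAAC_CODE[codes[start : start + w]], minlength=5)
        values.append(counts / w)
        names.extend(f"egaac.win{start + 1}.{g}" for g in _GAAC_NAMES)
    return names, np.concatenate(values)


def gdpc(seq: str, config: DescriptorConfig, tables: PropertyTableBundle):
    """Grouped dipeptide composition over ordered 5-group pairs."""
    codes = _check_sequence(seq)
    _require_length(seq, 2, "gdpc")
    g = _GAAC_CODE[codes]
    counts = np.zeros((5, 5))
    for a, b in zip(g[:-1], g[1:]):
        counts[a, b] += 1
    names = [
        f"gdpc.{ga}_{gb}" for ga in _GAAC_NAMES for gb in _GAAC_NAMES
    ]
    return names, counts.ravel() / (len(seq) - 1)


_DIPEPTIDES = ["".join(p) for p in itertools.product(AMINO_ACIDS, repeat=2)]
_CODONS = np.array([CODON_COUNTS[aa] for aa in AMINO_ACIDS], dtype=float)


def dde(seq: str, config: DescriptorConfig, tables: PropertyTableBundle):
    """Dipeptide deviation from expected mean (codon-background corrected)."""
    codes = _check_sequence(seq)
    _require_length(seq, 2, "dde")
    n = len(seq) - 1
    counts = np.zeros((20, 20))
    for a, b in zip(codes[:-1], codes[1:]):
        counts[a, b] += 1
    dc = counts.ravel() / n
    tm = np.outer(_CODONS / 61.0, _CODONS / 61.0).ravel()
    tv = tm * (1.0 - tm) / n
    values = (dc - tm) / np.sqrt(tv)
    names = [f"dde.{d}" for d in _DIPEPTIDES]
    return names, values


_CTD_MASKS: dict[str, np.ndarray] = {}
for _prop, _groups in CTD_GROUPS.items():
    code = np.empty(20, dtype=int)
    for _gi, _members in enumerate(_groups):
        for _aa in _members:
            code[_AA_INDEX[_aa]] = _gi
    _CTD_MASKS[_prop] = code


def ctdc(seq: str, config: DescriptorConfig, tables: PropertyTableBundle):
    """CTD Composition: per property, the three group fractions."""
    codes = _check_sequence(seq)
    names, values = [], []
    for prop, gcode in _CTD_MASKS.items():
        counts = np.bincount(gcode[codes], minlength=3)
        values.append(counts / len(seq))
        names.extend(f"ctdc.{prop}.g{k + 1}" for k in range(3))
    return names, np.concatenate(values)


_CTDD_POINTS = ("first", "p25", "p50", "p75", "last")


def ctdd(seq: str, config: DescriptorConfig, tables: PropertyTableBundle):
    """CTD Distribution: positional percentiles of each group's occurrences.

    For each property and group, the positions (percent of sequence length)
    of the first occurrence and of the residues at the ceil-25/50/75%
    quantiles and the last occurrence; absent groups contribute five zeros.
    """
    codes = _check_sequence(seq)
    L = len(seq)
    names, values = [], []
    for prop, gcode in _CTD_MASKS.items():
        membership = gcode[codes]
        for k in range(3):
            positions = np.flatnonzero(membership == k) + 1  # 1-based
            n = len(positions)
            if n == 0:
                block = np.zeros(5)
            else:
                idxs = [
                    1,
                    max(1, math.ceil(0.25 * n)),
                    max(1, math.ceil(0.50 * n)),
                    max(1, math.ceil(0.75 * n)),
                    n,
                ]
                block = np.array([positions[i - 1] for i in idxs]) * 100.0 / L
            values.append(block)
            names.extend(f"ctdd.{prop}.g{k + 1}.{pt}" for pt in _CTDD_POINTS)
    return names, np.concatenate(values)


# ---------------------------------------------------------------------------
# Positional encodings


def aaindex_encode(seq: str, config: DescriptorConfig, tables: PropertyTableBundle):
    """AAindex positional encoding: every index value at every position."""
    codes = _check_sequence(seq)
    tab = tables.aaindex.values  # (531, 20)
    block = tab[:, codes]  # (531, L)
    names = [
        f"aaindex.{acc}.pos{j + 1}"
        for acc in tables.aaindex.index
        for j in range(len(seq))
    ]
    return names, block.ravel()


def zscale_encode(seq: str, config: DescriptorConfig, tables: PropertyTableBundle):
    """Z-scale positional encoding (5 scales per position)."""
    codes = _check_sequence(seq)
    tab = tables.zscales.values  # (5, 20)
    block = tab[:, codes]
    names = [
        f"zscale.{z}.pos{j + 1}"
        for z in tables.zscales.index
        for j in range(len(seq))
    ]
    return names, block.ravel()


# ---------------------------------------------------------------------------
# Pseudo amino-acid composition families


def _standardized_props(tab: pd.DataFrame) -> np.ndarray:
    vals = tab.values
    mean = vals.mean(axis=1, keepdims=True)
    std = vals.std(axis=1, keepdims=True)
    return (vals - mean) / std


def paac(seq: str, config: DescriptorConfig, tables: PropertyTableBundle):
    """Chou's pseudo amino-acid composition (20 + lambda terms, sums to 1)."""
    codes = _check_sequence(seq)
    lam, w = config.lam, config.w
    _require_length(seq, lam + 1, "paac")
    props = _standardized_props(tables.paac_props)  # (3, 20)
    L = len(seq)
    theta = np.empty(lam)
    for j in range(1, lam + 1):
        a, b = codes[:-j], codes[j:]
        theta[j - 1] = np.mean(
            ((props[:, b] - props[:, a]) ** 2).mean(axis=0)
        )
    freqs = np.bincount(codes, minlength=20) / L
    denom = freqs.sum() + w * theta.sum()
    values = np.concatenate([freqs / denom, w * theta / denom])
    names = [f"paac.{aa}" for aa in AMINO_ACIDS] + [
        f"paac.lambda{j}" for j in range(1, lam + 1)
    ]
    return names, values


def apaac(seq: str, config: DescriptorConfig, tables: PropertyTableBundle):
    """Amphiphilic PAAC: 20 composition + 2*lambda hydropathy correlations."""
    codes = _check_sequence(seq)
    lam, w = config.lam, config.w
    _require_length(seq, lam + 1, "apaac")
    props = _standardized_props(tables.paac_props)[:2]  # hydrophobicity, hydrophilicity
    prop_names = list(tables.paac_props.index[:2])
    L = len(seq)
    tau = np.empty(2 * lam)
    for j in range(1, lam + 1):
        a, b = codes[:-j], codes[j:]
        for p in range(2):
            tau[2 * (j - 1) + p] = np.mean(props[p, a] * props[p, b])
    freqs = np.bincount(codes, minlength=20) / L
    denom = freqs.sum() + w * tau.sum()
    values = np.concatenate([freqs / denom, w * tau / denom])
    names = [f"apaac.{aa}" for aa in AMINO_ACIDS] + [
        f"apaac.lag{j}.{prop_names[p]}"
        for j in range(1, lam + 1)
        for p in range(2)
    ]
    return names, values


_QSO_MATRICES = ("physchem", "grantham")


def _distance_matrix(tables: PropertyTableBundle, which: str) -> np.ndarray:
    return (
        tables.physchem_distance if which == "physchem" else tables.grantham
    ).values


def socnumber(seq: str, config: DescriptorConfig, tables: PropertyTableBundle):
    """Sequence-order coupling numbers tau_d for both distance matrices."""
    codes = _check_sequence(seq)
    nlag = config.nlag
    _require_length(seq, nlag + 1, "socnumber")
    names, values = [], []
    for which in _QSO_MATRICES:
        dist = _distance_matrix(tables, which)
        for d in range(1, nlag + 1):
            tau = float((dist[codes[:-d], codes[d:]] ** 2).sum())
            values.append(tau)
            names.append(f"socnumber.{which}.lag{d}")
    return names, np.array(values)


def qsorder(seq: str, config: DescriptorConfig, tables: PropertyTableBundle):
    """Quasi-sequence-order: composition + coupling terms per matrix."""
    codes = _check_sequence(seq)
    nlag, w = config.nlag, config.qso_w
    _require_length(seq, nlag + 1, "qsorder")
    freqs = np.bincount(codes, minlength=20) / len(seq)
    names, values = [], []
    for which in _QSO_MATRICES:
        dist = _distance_matrix(tables, which)
        tau = np.array(
            [float((dist[codes[:-d], codes[d:]] ** 2).sum()) for d in range(1, nlag + 1)]
        )
        denom = freqs.sum() + w * tau.sum()
        values.append(freqs / denom)
        values.append(w * tau / denom)
        names.extend(f"qsorder.{which}.{aa}" for aa in AMINO_ACIDS)
        names.extend(f"qsorder.{which}.tau{d}" for d in range(1, nlag + 1))
    return names, np.concatenate(values)


# ---------------------------------------------------------------------------
# Autocorrelations


def _autocorr(seq, config, tables, kind: str):
    codes = _check_sequence(seq)
    nlag = config.nlag
    _require_length(seq, nlag + 1, kind)
    props = tables.autocorr_props.values  # (8, 20), already standardized
    L = len(seq)
    names, values = [], []
    for p, acc in enumerate(tables.autocorr_props.index):
        x = props[p, codes]
        xbar = x.mean()
        centred = x - xbar
        # a constant sequence has zero variance by definition; comparing
        # max==min avoids epsilon/epsilon artifacts from the float mean
        is_const = x.max() == x.min()
        var_moran = 0.0 if is_const else float((centred**2).mean())
        var_geary = (
            0.0 if is_const or L <= 1 else float((centred**2).sum() / (L - 1))
        )
        for d in range(1, nlag + 1):
            a, b = x[:-d], x[d:]
            if kind == "nmbroto":
                val = float((a * b).mean())
            elif kind == "moran":
                val = (
                    float(((a - xbar) * (b - xbar)).mean()) / var_moran
                    if var_moran > 0
                    else 0.0
                )
            else:  # geary
                val = (
                    float(((a - b) ** 2).sum() / (2 * (L - d))) / var_geary
                    if var_geary > 0
                    else 0.0
                )
            values.append(val)
            names.append(f"{kind}.{acc}.lag{d}")
    return names, np.array(values)


def nmbroto(seq, config, tables):
    """Normalized Moreau-Broto autocorrelation (8 properties x nlag)."""
    return _autocorr(seq, config, tables, "nmbroto")


def moran(seq, config, tables):
    """Moran autocorrelation; zero-variance sequences give 0 by convention."""
    return _autocorr(seq, config, tables, "moran")


def geary(seq, config, tables):
    """Geary autocorrelation; zero-variance sequences give 0 by convention."""
    return _autocorr(seq, config, tables, "geary")


FAMILY_FUNCTIONS: dict[str, Callable] = {
    "qsorder": qsorder,
    "socnumber": socnumber,
    "apaac": apaac,
    "paac": paac,
    "nmbroto": nmbroto,
    "geary": geary,
    "moran": moran,
    "aaindex": aaindex_encode,
    "zscale": zscale_encode,
    "egaac": egaac,
    "dde": dde,
    "gaac": gaac,
    "gdpc": gdpc,
    "ctdc": ctdc,
    "ctdd": ctdd,
}


# ---------------------------------------------------------------------------
# Whole-dataset extraction


@dataclass
class FeatureMatrix:
    """A named feature matrix aligned to a dataset (rows = records)."""

    ids: list[str]
    columns: list[str]
    values: np.ndarray
    labels: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.columns)):
            raise ValueError("feature matrix shape does not match ids/columns")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != len(self.ids):
                raise ValueError("labels length does not match ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        df.insert(0, "id", self.ids)
        if self.labels is not None:
            df.insert(1, "label", self.labels)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        ids = df.pop("id").astype(str).tolist()
        labels = df.pop("label").to_numpy(dtype=int) if "label" in df.columns else None
        return cls(ids=ids, columns=list(df.columns), values=df.to_numpy(float), labels=labels)


def extract_vector(
    seq: str,
    config: Optional[DescriptorConfig] = None,
    tables: Optional[PropertyTableBundle] = None,
) -> tuple[list[str], np.ndarray]:
    """Full named descriptor vector for one sequence."""
    config = config or DescriptorConfig()
    tables = tables if tables is not None else load_tables()
    names: list[str] = []
    chunks: list[np.ndarray] = []
    for fam in config.family_order:
        fam_names, fam_values = FAMILY_FUNCTIONS[fam](seq, config, tables)
        names.extend(fam_names)
        chunks.append(np.asarray(fam_values, dtype=float))
    return names, np.concatenate(chunks)


def extract_all(
    ds: LabeledDataset,
    config: Optional[DescriptorConfig] = None,
    tables: Optional[PropertyTableBundle] = None,
) -> FeatureMatrix:
    """Descriptor matrix for a whole dataset (rows in dataset order).

    All sequences must share one length compatible with the configuration;
    per-record failures are re-raised with the record id attached.
    """
    config = config or DescriptorConfig()
    tables = tables if tables is not None else load_tables()
    if len(ds) == 0:
        return FeatureMatrix(ids=[], columns=[], values=np.empty((0, 0)), labels=np.array([], dtype=int))
    lengths = {len(s) for s in ds.sequences}
    if len(lengths) > 1:
        raise DescriptorError(f"mixed sequence lengths {sorted(lengths)}")
    columns: Optional[list[str]] = None
    rows = []
    for rec in ds:
        try:
            names, vec = extract_vector(rec.sequence, config, tables)
        except DescriptorError as exc:
            raise DescriptorError(f"record {rec.id!r}: {exc}") from exc
        if columns is None:
            columns = names
        rows.append(vec)
    return FeatureMatrix(
        ids=ds.ids, columns=columns, values=np.vstack(rows), labels=ds.labels
    )
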