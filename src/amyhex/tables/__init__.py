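"""Physicochemical property tables backing the descriptor engine.

Numeric tables (AAindex, z-scales, PAAC properties, residue distance
matrices) are shipped as plain-text TSV files with a SHA-256 manifest;
categorical tables (residue groupings, codon counts) are defined here.

The pairwise residue distance matrix ``physchem_distance_synthetic.tsv``
is a synthetic stand-in for the Schneider-Wrede physicochemical distance
matrix: Euclidean distance over the three standardized PAAC properties
(hydrophobicity, hydrophilicity, side-chain mass), scaled to max 1.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

#: The 20 standard residues, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Five-way residue partition used by GAAC / EGAAC / GDPC.
GAAC_GROUPS = {
    "aliphatic": "GAVLMI",
    "aromatic": "FYW",
    "positive": "KRH",
    "negative": "DE",
    "uncharged": "STCPNQ",
}

#: Thirteen CTD properties, each a 3-way partition of the 20 residues.
CTD_GROUPS = {
    "hydrophobicity_PRAM900101": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "hydrophobicity_ARGP820101": ("QSTNGDE", "RAHCKMV", "LYPFIW"),
    "hydrophobicity_ZIMJ680101": ("QNGSWTDERA", "HMCKV", "LPFYI"),
    "hydrophobicity_PONP930101": ("KPDESNQT", "GRHA", "YMFWLCVI"),
    "hydrophobicity_CASG920101": ("KDEQPSRNTG", "AHYMLV", "FIWC"),
    "hydrophobicity_ENGD860101": ("RDKENQHYP", "SGTAW", "CVLIMF"),
    "hydrophobicity_FASG890101": ("KERSQD", "NTPG", "AYHWVMFLIC"),
    "normwaalsvolume": ("GASTCPD", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondarystruct": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solventaccess": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}

#: Codons per residue in the standard genetic code (sums to 61).
CODON_COUNTS = {
    "A": 4, "C": 2, "D": 2, "E": 2, "F": 2, "G": 4, "H": 2, "I": 3,
    "K": 2, "L": 6, "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6, "S": 6,
    "T": 4, "V": 4, "W": 1, "Y": 2,
}

#: AAindex accessions of the 8 properties used by the autocorrelation
#: descriptors (hydrophobicity, flexibility, polarizability, free energy,
#: accessible surface area, volume, steric parameter, relative mutability).
AUTOCORR_ACCESSIONS = (
    "CIDH920105", "BHAR880101", "CHAM820101", "CHAM820102",
    "CHOC760101", "BIGC670101", "CHAM810101", "DAYM780201",
)


class TableIntegrityError(RuntimeError):
    """A shipped property table failed its checksum."""


def _data_dir():
    return resources.files(__package__) / "data"


def _read_tsv(name: str) -> pd.DataFrame:
    with resources.as_file(_data_dir() / name) as path:
        return pd.read_csv(path, sep="\t")


@dataclass(frozen=True)
class PropertyTableBundle:
    """All numeric tables the descriptor families need, keyed by residue.

    Every table covers exactly the 20 standard residues in ``AMINO_ACIDS``
    order. Loaded once via :func:`load_tables`.
    """

    aaindex: pd.DataFrame          # 531 indices x 20 residues
    zscales: pd.DataFrame          # 5 scales x 20 residues
    paac_props: pd.DataFrame       # 3 properties x 20 residues
    autocorr_props: pd.DataFrame   # 8 standardized properties x 20 residues
    physchem_distance: pd.DataFrame  # 20 x 20 (synthetic Schneider-Wrede stand-in)
    grantham: pd.DataFrame           # 20 x 20

    def __post_init__(self):
        for name in ("aaindex", "zscales", "paac_props", "autocorr_props"):
            tab = getattr(self, name)
            if list(tab.columns) != list(AMINO_ACIDS):
                raise ValueError(f"table {name!r} must have columns {AMINO_ACIDS}")
            if tab.isna().any().any():
                raise ValueError(f"table {name!r} has missing values")
        for name in ("physchem_distance", "grantham"):
            tab = getattr(self, name)
            if list(tab.columns) != list(AMINO_ACIDS) or list(tab.index) != list(AMINO_ACIDS):
                raise ValueError(f"matrix {name!r} must be 20x20 over {AMINO_ACIDS}")


def verify_checksums() -> None:
    """Check every shipped table against the SHA-256 manifest.

    Raises
    ------
    TableIntegrityError
        If any file's digest differs from the manifest entry.
    """
    manifest = (_data_dir() / "manifest.sha256").read_text()
    for line in manifest.strip().splitlines():
        digest, name = line.split()
        data = (_data_dir() / name).read_bytes()
        actual = hashlib.sha256(data).hexdigest()
        if actual != digest:
            raise TableIntegrityError(f"{name}: expected {digest}, got {actual}")


def load_tables(verify: bool = True) -> PropertyTableBundle:
    """Load the bundled property tables.

    Parameters
    ----------
    verify : bool
        Verify the SHA-256 manifest before loading (cheap; default True).
    """
    if verify:
        verify_checksums()

    aa1 = _read_tsv("aaindex_1.tsv")
    aa2 = _read_tsv("aaindex_2.tsv")
    aaindex = pd.concat([aa1, aa2], ignore_index=True).set_index("accession")
    aaindex = aaindex[list(AMINO_ACIDS)]

    zscales = _read_tsv("zscales.tsv").set_index("residue").T
    zscales = zscales[list(AMINO_ACIDS)]

    paac = _read_tsv("paac_properties.tsv").set_index("residue").T
    paac = paac[list(AMINO_ACIDS)]

    auto = aaindex.loc[list(AUTOCORR_ACCESSIONS)]
    # standardized over the 20-residue table (population std)
    auto = auto.sub(auto.mean(axis=1), axis=0).div(auto.std(axis=1, ddof=0), axis=0)

    dist = _read_tsv("physchem_distance_synthetic.tsv").set_index("res")
    dist.index.name = None
    grantham = _read_tsv("grantham.tsv").set_index("res")
    grantham.index.name = None

    return PropertyTableBundle(
        aaindex=aaindex,
        zscales=zscales,
        paac_props=paac,
        autocorr_props=auto,
        physchem_distance=dist.loc[list(AMINO_ACIDS), list(AMINO_ACIDS)],
        grantham=grantham.loc[list(AMINO_ACIDS), list(AMINO_ACIDS)],
    )
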