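"""Descriptor-table data model, CSV I/O and the bundled 92-molecule fixture.

Each row is one NO-carrier molecule: its experimental homolysis BDE
(kcal/mol, measured by titration calorimetry in acetonitrile), the
B3LYP/6-31G(d) calculated homolysis BDE, eleven further descriptors from
the same calculation, and a train/test flag.  Units are kept exactly as
calculated: energies in a.u., enthalpies in kcal/mol, dipole moment in
debye, polarizability in a.u., charges in e.  No unit conversion happens
anywhere in the package: kernel distances downstream are taken on (scaled)
raw columns, and converting would silently change results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical descriptor column order (12 descriptors).
DESCRIPTOR_NAMES: tuple[str, ...] = (
    "dH_homo",    # calculated homolysis BDE, kcal/mol
    "Q_Y",        # net charge on the carrier atom Y, e
    "Q_N",        # net charge on N of the NO fragment, e
    "Q_O",        # net charge on O of the NO fragment, e
    "N_X",        # electron count of the fragment X (without NO)
    "mu",         # dipole moment, debye
    "alpha_pol",  # polarizability, a.u.
    "E_HOMO_m1",  # second-highest occupied MO energy, a.u.
    "E_HOMO",     # highest occupied MO energy, a.u.
    "E_LUMO",     # lowest unoccupied MO energy, a.u.
    "E_LUMO_p1",  # second-lowest unoccupied MO energy, a.u.
    "dE",         # E_LUMO - E_HOMO gap, a.u.
)

BOND_CLASSES = ("N-NO", "O-NO", "S-NO", "C-NO")

#: mol_id ranges of the fixture bond classes (inclusive).
FIXTURE_CLASS_RANGES: dict[str, tuple[int, int]] = {
    "N-NO": (1, 53),
    "O-NO": (54, 66),
    "S-NO": (67, 84),
    "C-NO": (85, 92),
}

_META_COLUMNS = ("mol_id", "bond_class", "split")
_FIXTURE_CSV = "yno_descriptors.csv"
_DEVIATIONS_CSV = "yno_reported_deviations.csv"


class TableError(ValueError):
    """Raised for schema, parse or integrity problems in a descriptor table."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule: identifiers, experimental BDE and its 12 descriptors."""

    mol_id: int
    bond_class: str
    expt_bde: float
    descriptors: Mapping[str, float]
    split: str = "train"

    def __post_init__(self) -> None:
        if self.mol_id <= 0:
            raise TableError(f"mol_id must be positive, got {self.mol_id}")
        if self.bond_class not in BOND_CLASSES:
            raise TableError(f"unknown bond class {self.bond_class!r}")
        if self.split not in ("train", "test"):
            raise TableError(f"split must be 'train' or 'test', got {self.split!r}")
        if not np.isfinite(self.expt_bde):
            raise TableError(f"non-finite expt_bde for molecule {self.mol_id}")
        for name, value in self.descriptors.items():
            if not np.isfinite(value):
                raise TableError(
                    f"non-finite descriptor {name!r} for molecule {self.mol_id}"
                )


@dataclass
class DescriptorTable:
    """Ordered collection of molecules with a shared descriptor registry.

    Thin, validated wrapper around a :class:`pandas.DataFrame` whose columns
    are ``mol_id, bond_class, split, expt_bde, <descriptors...>``.
    """

    df: pd.DataFrame
    descriptor_names: tuple[str, ...] = field(default=DESCRIPTOR_NAMES)

    def __post_init__(self) -> None:
        self.descriptor_names = tuple(self.descriptor_names)
        missing = [
            c
            for c in (*_META_COLUMNS, "expt_bde", *self.descriptor_names)
            if c not in self.df.columns
        ]
        if missing:
            raise TableError(f"missing required column(s): {missing}")
        self.df = self.df.reset_index(drop=True)
        ids = self.df["mol_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].tolist())
            raise TableError(f"duplicate mol_id(s): {dupes}")
        bad_split = ~self.df["split"].isin(["train", "test"])
        if bad_split.any():
            raise TableError(
                f"invalid split flag(s) for mol_id(s) "
                f"{self.df.loc[bad_split, 'mol_id'].tolist()}"
            )
        numeric = self.df[["expt_bde", *self.descriptor_names]]
        values = numeric.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise TableError("non-numeric value in a numeric column")
        if not np.isfinite(values).all():
            rows, cols = np.nonzero(~np.isfinite(values))
            raise TableError(
                f"non-finite value at mol_id "
                f"{self.df['mol_id'].iloc[rows[0]]}, column "
                f"{numeric.columns[cols[0]]!r}"
            )

    # -- basic shape ------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def m(self) -> int:
        return len(self.descriptor_names)

    @property
    def records(self) -> list[MoleculeRecord]:
        return [
            MoleculeRecord(
                mol_id=int(row.mol_id),
                bond_class=row.bond_class,
                expt_bde=float(row.expt_bde),
                descriptors={k: float(getattr(row, k)) for k in self.descriptor_names},
                split=row.split,
            )
            for row in self.df.itertuples(index=False)
        ]

    # -- numeric views ----------------------------------------------------
    def descriptor_matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        """n x m matrix of descriptor values (float), columns in ``names`` order."""
        names = self.descriptor_names if names is None else tuple(names)
        unknown = [c for c in names if c not in self.descriptor_names]
        if unknown:
            raise TableError(f"unknown descriptor(s): {unknown}")
        return self.df[list(names)].to_numpy(dtype=float)

    @property
    def expt(self) -> np.ndarray:
        return self.df["expt_bde"].to_numpy(dtype=float)

    @property
    def train_mask(self) -> np.ndarray:
        return (self.df["split"] == "train").to_numpy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DescriptorTable):
            return NotImplemented
        return self.descriptor_names == other.descriptor_names and self.df.equals(
            other.df
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_table(
    path: str | Path, schema: Sequence[str] = DESCRIPTOR_NAMES
) -> DescriptorTable:
    """Read a descriptor CSV.

    The file must have a header row with at least ``mol_id, bond_class,
    expt_bde`` and every descriptor in ``schema``.  A missing ``split``
    column defaults every record to ``train``.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["mol_id", "bond_class", "expt_bde", *schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableError(f"{path.name}: missing required column(s): {missing}")
    if "split" not in df.columns:
        df["split"] = "train"
    for col in ("expt_bde", *schema):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise TableError(
                f"{path.name}: non-numeric value {df[col].iloc[row]!r} "
                f"at row {row + 2}, column {col!r}"
            )
        df[col] = converted
    df["mol_id"] = df["mol_id"].astype(int)
    order = ["mol_id", "bond_class", "split", "expt_bde", *schema]
    return DescriptorTable(df[order], tuple(schema))


def write_table(table: DescriptorTable, path: str | Path) -> None:
    """Write a table as CSV such that ``read_table(path) == table``.

    Floats are written with :func:`repr` precision, so the round trip is
    bit-exact.
    """
    cols = ["mol_id", "bond_class", "split", "expt_bde", *table.descriptor_names]
    table.df[cols].to_csv(path, index=False)


def load_fixture() -> DescriptorTable:
    """Load the packaged 92-molecule Y-NO table.

    Returns the table of experimental homolysis BDE values, B3LYP/6-31G(d)
    descriptors, and the fixed 80/12 train/test split.  The packaged file is
    integrity-checked: the orbital-gap identity dE = E_LUMO - E_HOMO must
    hold within rounding (5e-4 a.u.) and the bond classes must match the
    documented mol_id ranges.
    """
    with resources.as_file(
        resources.files("ynobde").joinpath("data", _FIXTURE_CSV)
    ) as p:
        table = read_table(p)
    if table.n != 92:
        raise TableError(f"fixture corrupted: expected 92 rows, found {table.n}")
    gap = table.df["E_LUMO"] - table.df["E_HOMO"]
    bad = (table.df["dE"] - gap).abs() > 5e-4
    if bad.any():
        raise TableError(
            "fixture corrupted: dE != E_LUMO - E_HOMO at mol_id(s) "
            f"{table.df.loc[bad, 'mol_id'].tolist()}"
        )
    for cls, (lo, hi) in FIXTURE_CLASS_RANGES.items():
        block = table.df[(table.df.mol_id >= lo) & (table.df.mol_id <= hi)]
        wrong = block[block.bond_class != cls]
        if len(wrong):
            raise TableError(
                f"fixture corrupted: bond_class mismatch at mol_id(s) "
                f"{wrong.mol_id.tolist()} (expected {cls})"
            )
    n_test = int((~table.train_mask).sum())
    if n_test != 12:
        raise TableError(f"fixture corrupted: expected 12 test molecules, {n_test}")
    return table


def load_reported_deviations() -> pd.DataFrame:
    """Packaged per-molecule deviations (experimental minus calculated).

    Columns: ``mol_id, expt_bde, dev_b3lyp, dev_f_grnn, dev_g_grnn,
    dev_gp_grnn`` -- the uncorrected B3LYP deviation and the published
    deviations of the three corrected variants, for cross-validation of the
    fixture and for reference comparisons.
    """
    with resources.as_file(
        resources.files("ynobde").joinpath("data", _DEVIATIONS_CSV)
    ) as p:
        return pd.read_csv(p)


def validate_against_deviations(
    table: DescriptorTable,
    b3lyp_deviations: Mapping[int, float],
    tol: float = 0.01,
) -> list[tuple[int, float, float]]:
    """Cross-check ``expt_bde - dH_homo`` against reference deviations.

    Parameters
    ----------
    b3lyp_deviations
        Mapping ``mol_id -> expected deviation`` (kcal/mol).
    tol
        Allowed absolute discrepancy (two-decimal rounding gives 0.01).

    Returns
    -------
    list of (mol_id, computed, expected) violations; empty when consistent.

    Raises
    ------
    KeyError
        If a deviation is keyed by an unknown ``mol_id``.
    """
    ids = set(table.df["mol_id"].tolist())
    unknown = [k for k in b3lyp_deviations if k not in ids]
    if unknown:
        raise KeyError(f"unknown mol_id(s): {sorted(unknown)}")
    violations = []
    sub = table.df.set_index("mol_id")
    for mol_id, expected in b3lyp_deviations.items():
        computed = float(sub.loc[mol_id, "expt_bde"] - sub.loc[mol_id, "dH_homo"])
        if abs(computed - expected) > tol + 1e-12:
            violations.append((mol_id, computed, float(expected)))
    return violations
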