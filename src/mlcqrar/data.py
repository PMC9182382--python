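"""Compound tables: the embedded 15-compound study dataset and CSV I/O.

The dataset couples micellar-chromatography lipophilicity descriptors
(log k_m, log K_AM) for 15 carbamic-acid (group I) and phenoxyacetic-acid
(group II) derivatives with in-silico molecular descriptors (log P, HBD,
HBA, NRB, MW, TPSA) and pharmacokinetic/toxicity endpoints (V_d, unbound
fractions, log BB, skin/cell permeation, albumin binding, plant-cuticle
partitioning, mouse oral LD50).

Tables are rectangular; missing values are explicit (NaN) and any modelling
operation that consumes a column containing them fails loudly, because the
embedded dataset is complete.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import (
    MissingFieldError,
    ParseError,
    SchemaError,
    ValidationError,
)

#: canonical column roles for the embedded dataset
IDENTIFIER_COLUMNS = ("compound_id", "group")
DESCRIPTOR_COLUMNS = (
    "log_km", "log_KAM", "log_P", "HBD", "HBA", "NRB", "MW", "TPSA",
)
ENDPOINT_COLUMNS = (
    "Vd", "fu_plasma", "fu_brain", "log_BB", "log_Kp", "log_Ksc",
    "log_Kwcell", "log_PwHSA", "log_KHSA", "log_Pwpc", "LD50",
)

#: columns that must hold non-negative integers
_COUNT_COLUMNS = ("HBD", "HBA", "NRB")

FIXTURE_SCHEMA: dict[str, str] = {
    **{c: "identifier" for c in IDENTIFIER_COLUMNS},
    **{c: "descriptor" for c in DESCRIPTOR_COLUMNS},
    **{c: "endpoint" for c in ENDPOINT_COLUMNS},
}

_ROLES = ("identifier", "descriptor", "endpoint")

# Unicode dashes occasionally pasted into CSVs; normalised to ASCII '-'.
_MINUS_TRANSLATION = str.maketrans({"−": "-", "–": "-", "—": "-"})


@dataclass(frozen=True)
class CompoundRecord:
    """One compound: identifiers, descriptors and endpoint values.

    Fields not present in the source table are ``None``.
    """

    compound_id: int
    group: str | None = None
    log_km: float | None = None
    log_KAM: float | None = None
    log_P: float | None = None
    HBD: int | None = None
    HBA: int | None = None
    NRB: int | None = None
    MW: float | None = None
    TPSA: float | None = None
    Vd: float | None = None
    fu_plasma: float | None = None
    fu_brain: float | None = None
    log_BB: float | None = None
    log_Kp: float | None = None
    log_Ksc: float | None = None
    log_Kwcell: float | None = None
    log_PwHSA: float | None = None
    log_KHSA: float | None = None
    log_Pwpc: float | None = None
    LD50: float | None = None


@dataclass
class CompoundTable:
    """Rectangular compound table with column-role metadata.

    Parameters
    ----------
    frame
        Underlying data, one row per compound.
    descriptor_names, endpoint_names
        Columns playing the descriptor / endpoint roles.  Together with the
        identifier columns they must partition ``frame``'s columns; no
        column may carry two roles.
    """

    frame: pd.DataFrame
    descriptor_names: tuple[str, ...] = DESCRIPTOR_COLUMNS
    endpoint_names: tuple[str, ...] = ENDPOINT_COLUMNS
    identifier_names: tuple[str, ...] = field(default=IDENTIFIER_COLUMNS)

    def __post_init__(self) -> None:
        self.descriptor_names = tuple(self.descriptor_names)
        self.endpoint_names = tuple(self.endpoint_names)
        self.identifier_names = tuple(
            c for c in self.identifier_names if c in self.frame.columns
        )
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        """Check role partition and per-column domain invariants."""
        roles: dict[str, str] = {}
        for role, names in (
            ("identifier", self.identifier_names),
            ("descriptor", self.descriptor_names),
            ("endpoint", self.endpoint_names),
        ):
            for name in names:
                if name in roles:
                    raise ValidationError(
                        f"column {name!r} assigned two roles "
                        f"({roles[name]} and {role})"
                    )
                if name not in self.frame.columns:
                    raise SchemaError(f"column {name!r} not present in table")
                roles[name] = role
        extra = set(self.frame.columns) - set(roles)
        if extra:
            raise SchemaError(f"columns without a role: {sorted(extra)}")

        if "compound_id" in self.frame.columns:
            ids = self.frame["compound_id"]
            if ids.duplicated().any():
                dupes = sorted(ids[ids.duplicated()].unique().tolist())
                raise ValidationError(f"duplicate compound_id values: {dupes}")
            if (ids <= 0).any():
                raise ValidationError("compound_id values must be positive")

        self._check_bounds("fu_plasma", lower=0.0, upper=1.0,
                           lower_open=True)
        self._check_bounds("fu_brain", lower=0.0, upper=1.0, lower_open=True)
        self._check_bounds("LD50", lower=0.0, lower_open=True)
        self._check_bounds("MW", lower=0.0, lower_open=True)
        self._check_bounds("TPSA", lower=0.0)
        for name in _COUNT_COLUMNS:
            if name not in self.frame.columns:
                continue
            col = self.frame[name].dropna()
            vals = col.to_numpy(dtype=float)
            if not np.all(vals == np.round(vals)) or (vals < 0).any():
                bad = self._offending_rows(name, (vals != np.round(vals)) |
                                           (vals < 0), col.index)
                raise ValidationError(
                    f"column {name!r} must hold non-negative integers; "
                    f"violated in rows {bad}"
                )

    def _check_bounds(self, name: str, lower: float | None = None,
                      upper: float | None = None,
                      lower_open: bool = False) -> None:
        if name not in self.frame.columns:
            return
        col = self.frame[name].dropna()
        vals = col.to_numpy(dtype=float)
        bad = np.zeros(len(vals), dtype=bool)
        if lower is not None:
            bad |= vals < lower if not lower_open else vals <= lower
        if upper is not None:
            bad |= vals > upper
        if bad.any():
            rows = self._offending_rows(name, bad, col.index)
            bounds = f"({lower}, {upper}]" if lower_open else f"[{lower}, {upper}]"
            raise ValidationError(
                f"column {name!r} out of bounds {bounds} in rows {rows}"
            )

    def _offending_rows(self, name: str, mask: np.ndarray,
                        index: pd.Index) -> list[int]:
        # 1-based data-row numbers, as counted below the header
        positions = self.frame.index.get_indexer(index[mask])
        return [int(p) + 1 for p in positions]

    # -- access -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> list[CompoundRecord]:
        known = {f for f in CompoundRecord.__dataclass_fields__}
        out = []
        for row in self.frame.to_dict(orient="records"):
            kwargs = {k: v for k, v in row.items() if k in known}
            for c in ("compound_id", *_COUNT_COLUMNS):
                if c in kwargs and kwargs[c] is not None and not pd.isna(kwargs[c]):
                    kwargs[c] = int(kwargs[c])
            out.append(CompoundRecord(**kwargs))
        return out

    def record(self, compound_id: int) -> CompoundRecord:
        """Return the record for one compound by its identifier."""
        match = self.frame.loc[self.frame["compound_id"] == compound_id]
        if match.empty:
            raise KeyError(f"no compound with id {compound_id}")
        sub = CompoundTable(match, self.descriptor_names,
                            self.endpoint_names, self.identifier_names)
        return sub.records[0]

    def column(self, name: str) -> np.ndarray:
        """Numeric column as a float array; fails loudly on missing values."""
        if name not in self.frame.columns:
            raise SchemaError(f"no column {name!r} in table")
        col = self.frame[name]
        if col.isna().any():
            rows = [int(i) + 1 for i in np.flatnonzero(col.isna().to_numpy())]
            raise MissingFieldError(
                f"column {name!r} has missing values in rows {rows}"
            )
        return col.to_numpy(dtype=float)

    def subset(self, mask: Iterable[bool]) -> "CompoundTable":
        frame = self.frame.loc[np.asarray(list(mask), dtype=bool)]
        return CompoundTable(frame.reset_index(drop=True),
                             self.descriptor_names, self.endpoint_names,
                             self.identifier_names)

    def equals(self, other: "CompoundTable") -> bool:
        if list(self.frame.columns) != list(other.frame.columns):
            return False
        a = self.frame.reset_index(drop=True)
        b = other.frame.reset_index(drop=True)
        if len(a) != len(b):
            return False
        for c in a.columns:
            if a[c].dtype.kind in "if" and b[c].dtype.kind in "if":
                av, bv = a[c].to_numpy(float), b[c].to_numpy(float)
                ok = (av == bv) | (np.isnan(av) & np.isnan(bv))
                if not ok.all():
                    return False
            elif not a[c].astype(str).equals(b[c].astype(str)):
                return False
        return True


# -- I/O -------------------------------------------------------------------

def read_compound_table(source: str | IO[str],
                        schema: Mapping[str, str] | None = None,
                        ) -> CompoundTable:
    """Read a delimited compound table, validating against a role schema.

    Parameters
    ----------
    source
        Path or text stream holding comma-delimited data with a header row.
    schema
        Mapping from header name to role (``identifier`` / ``descriptor`` /
        ``endpoint``).  Defaults to the embedded dataset's schema.

    Raises
    ------
    SchemaError
        If a mapped column is absent (or a role name is unknown).
    ParseError
        If a numeric cell cannot be parsed; the message names row and column.
    ValidationError
        If a domain invariant is violated; the message names the rows.
    """
    schema = dict(schema) if schema is not None else dict(FIXTURE_SCHEMA)
    for name, role in schema.items():
        if role not in _ROLES:
            raise SchemaError(f"unknown role {role!r} for column {name!r}")

    raw = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in schema if c not in raw.columns]
    if missing:
        raise SchemaError(f"schema columns missing from input: {missing}")
    raw = raw[[c for c in raw.columns if c in schema]]

    data: dict[str, pd.Series] = {}
    for name in raw.columns:
        cleaned = raw[name].str.strip().str.translate(_MINUS_TRANSLATION)
        if name == "group" or (schema[name] == "identifier"
                               and name != "compound_id"):
            data[name] = cleaned
            continue
        numeric = pd.to_numeric(cleaned.replace("", np.nan), errors="coerce")
        bad = numeric.isna() & (cleaned != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ParseError(
                f"cannot parse {cleaned[bad].iloc[0]!r} as a number "
                f"(row {row}, column {name!r})"
            )
        data[name] = numeric

    frame = pd.DataFrame(data)
    if "compound_id" in frame.columns and not frame["compound_id"].isna().any():
        frame["compound_id"] = frame["compound_id"].astype(int)
    for c in _COUNT_COLUMNS:
        if c in frame.columns and not frame[c].isna().any():
            if (frame[c] == frame[c].round()).all():
                frame[c] = frame[c].astype(int)

    roles = {r: tuple(c for c in frame.columns if schema[c] == r)
             for r in _ROLES}
    return CompoundTable(frame,
                         descriptor_names=roles["descriptor"],
                         endpoint_names=roles["endpoint"],
                         identifier_names=roles["identifier"])


def write_compound_table(table: CompoundTable, sink: str | IO[str]) -> None:
    """Write a compound table as comma-delimited UTF-8 text.

    Output is ASCII (no typographic minus signs) and round-trips through
    :func:`read_compound_table` exactly.
    """
    try:
        table.frame.to_csv(sink, index=False)
    except OSError as exc:  # pragma: no cover - I/O environment specific
        raise OSError(f"failed writing compound table to {sink!r}: {exc}")


def load_fixture() -> CompoundTable:
    """Load the embedded 15-compound study dataset."""
    text = resources.files("mlcqrar").joinpath(
        "assets/compounds.csv").read_text()
    return read_compound_table(io.StringIO(text))
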