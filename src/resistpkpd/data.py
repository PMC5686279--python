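"""Long-format observation tables (NONMEM-style columns).

One row per event: observations (``EVID=0``) carry a value ``DV`` of kind
``DVID`` (``pk`` in ug/L or ``tumor`` in mm3) and a BLQ flag; dose events
(``EVID=1``) carry ``AMT`` in mg/kg.  ``GROUP`` is the dose group
(vehicle/low/mid/high) and ``COMPOUND`` the administered drug.

Files are plain delimited text with a schema/units header so units are
asserted, not assumed.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .dosing import DosingRegimen
from .errors import SchemaError

__all__ = ["ObservationTable", "COLUMNS"]

SCHEMA = "resistpkpd-obs v1"
UNITS = "TIME=d DV.pk=ug/L DV.tumor=mm3 AMT=mg/kg"
COLUMNS = ["ID", "TIME", "EVID", "DVID", "DV", "AMT", "BLQ", "GROUP", "COMPOUND"]
GROUPS = {"vehicle", "low", "mid", "high"}


class ObservationTable:
    """Validated long-format PK/tumor observation table.

    Wraps a DataFrame with the fixed column set; provides per-subject
    regimen extraction and optional attachment of individual PK parameters
    for sequential PK-then-PD fitting.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        self.df = df.reset_index(drop=True)
        self.pk_params: dict | None = None  # ID -> PKParameters, attached later
        if validate:
            self.validate()

    def validate(self) -> None:
        df = self.df
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        bad = df.index[df["TIME"] < 0].tolist()
        if bad:
            raise SchemaError(f"negative TIME in rows {bad[:10]}")
        if not df["EVID"].isin([0, 1]).all():
            raise SchemaError("EVID must be 0 (observation) or 1 (dose)")
        obs = df[df["EVID"] == 0]
        if not obs["DVID"].isin(["pk", "tumor"]).all():
            raise SchemaError("observation DVID must be 'pk' or 'tumor'")
        bad = obs.index[(obs["DV"] <= 0) & (obs["BLQ"] == 0)].tolist()
        if bad:
            raise SchemaError(f"non-positive DV without BLQ flag in rows {bad[:10]}")
        if not df["GROUP"].isin(GROUPS).all():
            raise SchemaError(f"GROUP must be one of {sorted(GROUPS)}")
        doses = df[df["EVID"] == 1]
        if (doses["AMT"] < 0).any():
            raise SchemaError("dose AMT must be >= 0")
        veh = df[df["GROUP"] == "vehicle"]
        if (veh["EVID"] == 1).any():
            raise SchemaError("vehicle subjects must not have dose events")

    # -- accessors ---------------------------------------------------------

    @property
    def subjects(self) -> list:
        return list(pd.unique(self.df["ID"]))

    def observations(self, dvid: str | None = None, subject=None,
                     drop_blq: bool = False) -> pd.DataFrame:
        df = self.df[self.df["EVID"] == 0]
        if dvid is not None:
            df = df[df["DVID"] == dvid]
        if subject is not None:
            df = df[df["ID"] == subject]
        if drop_blq:
            df = df[df["BLQ"] == 0]
        return df

    def regimen_for(self, subject) -> DosingRegimen:
        rows = self.df[(self.df["ID"] == subject) & (self.df["EVID"] == 1)]
        sub = self.df[self.df["ID"] == subject]
        if sub.empty:
            raise SchemaError(f"unknown subject {subject!r}")
        compound = sub["COMPOUND"].iloc[0]
        events = tuple(zip(rows["TIME"].to_numpy(float), rows["AMT"].to_numpy(float)))
        return DosingRegimen(events, compound)

    def group_of(self, subject) -> str:
        return str(self.df.loc[self.df["ID"] == subject, "GROUP"].iloc[0])

    def compound_of(self, subject) -> str:
        return str(self.df.loc[self.df["ID"] == subject, "COMPOUND"].iloc[0])

    def attach_pk(self, pk_params: dict) -> "ObservationTable":
        """Attach per-subject PK parameters (sequential fitting input)."""
        missing = [s for s in self.subjects if s not in pk_params
                   and self.compound_of(s) != "vehicle"]
        if missing:
            raise SchemaError(f"no PK parameters for subjects {missing[:5]}")
        self.pk_params = dict(pk_params)
        return self

    def fingerprint(self) -> str:
        """Hash of the observation rows; used to check fits share a dataset."""
        import hashlib
        obs = self.observations().sort_values(["ID", "TIME", "DVID"])
        buf = obs[["ID", "TIME", "DVID", "DV", "BLQ"]].to_csv(index=False)
        return hashlib.sha256(buf.encode()).hexdigest()[:16]

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# schema: {SCHEMA}\n# units: {UNITS}\n")
            self.df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "ObservationTable":
        with open(path) as fh:
            header = [fh.readline(), fh.readline()]
            body = fh.read()
        if not header[0].startswith("# schema:") or SCHEMA not in header[0]:
            raise SchemaError(f"unrecognized schema header in {path}")
        if not header[1].startswith("# units:") or UNITS not in header[1]:
            raise SchemaError(f"unit declaration mismatch in {path}; expected {UNITS!r}")
        df = pd.read_csv(io.StringIO(body),
                         dtype={"ID": str, "DVID": str, "GROUP": str, "COMPOUND": str})
        df["DVID"] = df["DVID"].fillna("")
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ObservationTable):
            return NotImplemented
        a = self.df.fillna(-1)
        b = other.df.fillna(-1)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in a.columns:
            av, bv = a[c].to_numpy(), b[c].to_numpy()
            if av.dtype.kind == "f" or bv.dtype.kind == "f":
                if not np.allclose(av.astype(float), bv.astype(float),
                                   rtol=1e-9, atol=1e-9, equal_nan=True):
                    return False
            elif not (av.astype(str) == bv.astype(str)).all():
                return False
        return True
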