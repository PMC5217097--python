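"""Readers and writers for event-history data and analysis configs.

The single subject-level input format is a long-format CSV with columns
``id, arm, time, event``: one row per observed transition (``event`` is a
component label) plus at most one ``censor`` row per subject, marking the
end of follow-up for subjects not absorbed earlier.  Times are strictly
positive; row order in the file is irrelevant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .chibarsq import Cone, cone_validate, nonneg_cone, ordered_cone
from .estimation import MultistateTree
from .event_model import ComponentSet, SubjectHistory

__all__ = [
    "read_event_history",
    "write_event_history",
    "records_to_frame",
    "load_tree",
    "parse_cone",
]

CENSOR = "censor"
REQUIRED_COLUMNS = ["id", "arm", "time", "event"]


def read_event_history(path, components: ComponentSet | None = None) -> dict:
    """Parse an event-history CSV into per-arm lists of SubjectHistory.

    ``components`` optionally restricts the admissible event labels.
    Raises a distinct ValueError for a missing header, unknown labels,
    non-positive times, duplicate censor rows, or a censor row that is not
    last.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns {missing} (header required)")
    if df.empty:
        raise ValueError("event-history file contains no rows")
    if components is not None:
        valid = set(components.labels) | {CENSOR}
        bad = set(df["event"].astype(str)) - valid
        if bad:
            raise ValueError(f"unknown event labels {sorted(bad)}")
    if (df["time"] <= 0).any():
        raise ValueError("times must be strictly positive")

    out: dict = {}
    for (arm, sid), grp in df.groupby(["arm", "id"], sort=True):
        grp = grp.sort_values("time", kind="mergesort")
        cens = grp[grp["event"].astype(str) == CENSOR]
        if len(cens) > 1:
            raise ValueError(f"subject {sid!r} has duplicate censor rows")
        censor_time = None
        if len(cens) == 1:
            censor_time = float(cens["time"].iloc[0])
            ev = grp[grp["event"].astype(str) != CENSOR]
            if len(ev) and ev["time"].max() > censor_time:
                raise ValueError(f"subject {sid!r}: censor row is not last")
        else:
            ev = grp
        events = tuple(
            (float(t), str(e)) for t, e in zip(ev["time"], ev["event"])
        )
        rec = SubjectHistory(
            subject_id=str(sid), arm=str(arm), events=events, censor_time=censor_time
        )
        out.setdefault(str(arm), []).append(rec)
    return out


def records_to_frame(records) -> pd.DataFrame:
    """Flatten SubjectHistory records to the long CSV schema."""
    rows = []
    for rec in records:
        for t, e in rec.events:
            rows.append((rec.subject_id, rec.arm, t, e))
        if rec.censor_time is not None:
            rows.append((rec.subject_id, rec.arm, rec.censor_time, CENSOR))
    return pd.DataFrame(rows, columns=REQUIRED_COLUMNS)


def write_event_history(records, path) -> None:
    records_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def load_tree(path) -> MultistateTree:
    """Load a multistate-tree specification from YAML.

    Expected keys: ``states`` (list, first entry or ``root`` is the root),
    ``edges`` (list of [from, to] or [from, to, hazard]), ``components``
    (map state -> list of component labels).
    """
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    states = tuple(spec["states"])
    root = spec.get("root", states[0])
    edges, hazards = [], {}
    has_rates = False
    for e in spec["edges"]:
        a, b = e[0], e[1]
        edges.append((a, b))
        if len(e) > 2:
            hazards[(a, b)] = float(e[2])
            has_rates = True
    comp = {s: frozenset(v) for s, v in spec["components"].items()}
    return MultistateTree(
        states=states,
        edges=tuple(edges),
        state_components=comp,
        hazards=hazards if has_rates else None,
        root=root,
    )


def parse_cone(spec: str, K: int) -> Cone:
    """Expand a cone shorthand (``nonneg`` / ``ordered``) or load a YAML
    file with ``A_eq`` and ``A_ineq`` row lists."""
    if spec == "nonneg":
        return nonneg_cone(K)
    if spec == "ordered":
        return ordered_cone(K)
    with open(spec) as fh:
        data = yaml.safe_load(fh)
    A_eq = np.array(data.get("A_eq", []), dtype=float) if data.get("A_eq") else None
    A_ineq = np.array(data["A_ineq"], dtype=float)
    return cone_validate(A_eq, A_ineq)
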