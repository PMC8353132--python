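"""Delimited-text I/O for item banks, response matrices and score tables.

Item bank CSV columns (one row per item):

``item_id``
    opaque label
``kind``
    ``dichotomous`` or ``polytomous``
``occasion``
    ``pretest`` or ``posttest`` (ignored for unidimensional forms)
``a``
    discrimination (dichotomous only; blank means 1)
``b``
    difficulty (dichotomous only)
``b1..bH``
    step parameters (polytomous only; trailing blanks allowed for items
    with fewer categories)

Response matrix CSV: one row per examinee, first column ``examinee_id``,
then one column per item (named by ``item_id``, in form order) holding
integer codes: 0/1 for dichotomous items, 1..h for polytomous items, and
an empty cell for an item not administered to that examinee.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .models import (
    DICHOTOMOUS,
    Item,
    LONGITUDINAL,
    POLYTOMOUS,
    POSTTEST,
    TestForm,
    UNIDIMENSIONAL,
)

__all__ = ["write_item_bank", "read_item_bank", "write_responses", "read_responses"]


def write_item_bank(form: TestForm, path) -> None:
    hmax = max((it.n_categories for it in form.items if it.kind == POLYTOMOUS), default=0)
    rows = []
    for it in form.items:
        row = {"item_id": it.item_id, "kind": it.kind, "occasion": it.occasion,
               "a": np.nan, "b": np.nan}
        if it.kind == DICHOTOMOUS:
            row["a"] = it.discrimination
            row["b"] = it.difficulty
        else:
            for j, s in enumerate(it.steps, start=1):
                row[f"b{j}"] = s
        rows.append(row)
    cols = ["item_id", "kind", "occasion", "a", "b"] + [f"b{j}" for j in range(1, hmax + 1)]
    pd.DataFrame(rows).reindex(columns=cols).to_csv(path, index=False)


def read_item_bank(path, regime: Optional[str] = None) -> TestForm:
    """Read a calibrated item bank.  The regime defaults to longitudinal
    when any item is assigned to the posttest, unidimensional otherwise."""
    df = pd.read_csv(path)
    required = {"item_id", "kind", "occasion"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"item bank is missing columns {sorted(missing)}")
    step_cols = sorted(
        (c for c in df.columns if c.startswith("b") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    items = []
    for _, row in df.iterrows():
        kind = str(row["kind"]).strip()
        occ = str(row["occasion"]).strip()
        if kind == DICHOTOMOUS:
            a = row.get("a", np.nan)
            items.append(
                Item(
                    str(row["item_id"]), kind, occ,
                    difficulty=float(row["b"]),
                    discrimination=1.0 if pd.isna(a) else float(a),
                )
            )
        else:
            steps = tuple(
                float(row[c]) for c in step_cols if not pd.isna(row.get(c, np.nan))
            )
            items.append(Item(str(row["item_id"]), kind, occ, steps=steps))
    if regime is None:
        regime = (
            LONGITUDINAL
            if any(it.occasion == POSTTEST for it in items)
            else UNIDIMENSIONAL
        )
    return TestForm(tuple(items), regime)


def write_responses(path, responses: np.ndarray, form: TestForm, ids=None) -> None:
    R = np.asarray(responses)
    if R.ndim == 1:
        R = R[None, :]
    if ids is None:
        ids = [f"p{i + 1:04d}" for i in range(R.shape[0])]
    df = pd.DataFrame(R, columns=[it.item_id for it in form.items])
    df.insert(0, "examinee_id", ids)
    df.to_csv(path, index=False)


def read_responses(path, form: TestForm) -> Tuple[list, np.ndarray]:
    """Read a response matrix aligned to a form.

    Returns ``(examinee_ids, R)`` where ``R`` is a float matrix with NaN
    marking items not administered (complete rows can be cast to int).
    """
    df = pd.read_csv(path)
    if df.columns[0] != "examinee_id":
        raise ValueError("first response column must be 'examinee_id'")
    want = [it.item_id for it in form.items]
    missing = [c for c in want if c not in df.columns]
    if missing:
        raise ValueError(f"response matrix is missing item columns {missing[:5]}")
    R = df[want].to_numpy(dtype=float)
    return list(df["examinee_id"]), R
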