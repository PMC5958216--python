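"""Headered-CSV round trips for the study's matrices.

Every writer puts a one-line ``#``-prefixed provenance comment (seed,
condition id, whatever the caller supplies) above the header; readers skip
comment lines.  Q-matrices and item parameters are written items-as-rows,
profile and response matrices examinees-as-rows.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dina import AttributeProfileMatrix, ItemParameterSet, QMatrix, ResponseMatrix

__all__ = [
    "write_qmatrix",
    "read_qmatrix",
    "write_item_parameters",
    "read_item_parameters",
    "write_profiles",
    "read_profiles",
    "write_responses",
    "read_responses",
]


def _write(path, frame: pd.DataFrame, provenance: str | None) -> None:
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        frame.to_csv(fh, index=False)


def write_qmatrix(q: QMatrix, path: str | Path, provenance: str | None = None) -> None:
    frame = pd.DataFrame(
        q.entries, columns=[f"attr{a}" for a in q.attribute_ids]
    )
    frame.insert(0, "item_id", q.item_ids)
    _write(path, frame, provenance)


def read_qmatrix(path: str | Path) -> QMatrix:
    frame = pd.read_csv(path, comment="#")
    item_ids = tuple(int(i) for i in frame.pop("item_id"))
    attr_ids = tuple(int(c.removeprefix("attr")) for c in frame.columns)
    return QMatrix(frame.to_numpy(dtype=np.int8), item_ids, attr_ids)


def write_item_parameters(
    params: ItemParameterSet, path: str | Path, provenance: str | None = None
) -> None:
    frame = pd.DataFrame(
        {
            "item_id": np.arange(1, params.n_items + 1),
            "slipping": params.slipping,
            "guessing": params.guessing,
        }
    )
    _write(path, frame, provenance)


def read_item_parameters(path: str | Path) -> ItemParameterSet:
    frame = pd.read_csv(path, comment="#")
    return ItemParameterSet(
        frame["slipping"].to_numpy(float), frame["guessing"].to_numpy(float)
    )


def write_profiles(
    profiles: AttributeProfileMatrix, path: str | Path, provenance: str | None = None
) -> None:
    frame = pd.DataFrame(
        profiles.profiles,
        columns=[f"attr{k}" for k in range(1, profiles.n_attributes + 1)],
    )
    _write(path, frame, provenance)


def read_profiles(path: str | Path, generating_correlation: float = float("nan")) -> AttributeProfileMatrix:
    frame = pd.read_csv(path, comment="#")
    return AttributeProfileMatrix(frame.to_numpy(dtype=np.int8), generating_correlation)


def write_responses(
    x: ResponseMatrix, path: str | Path, provenance: str | None = None
) -> None:
    frame = pd.DataFrame(
        x.responses, columns=[f"item{j}" for j in range(1, x.n_items + 1)]
    )
    _write(path, frame, provenance)


def read_responses(path: str | Path, group_label: str = "reference") -> ResponseMatrix:
    frame = pd.read_csv(path, comment="#")
    return ResponseMatrix(frame.to_numpy(dtype=np.int8), group_label)
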