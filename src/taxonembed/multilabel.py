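"""Multilabel target construction over hosts and taxonomic ranks.

Each instance gets a binary vector O = (o_1 ... o_C) laid out in blocks:
the host block first, then one block per selected rank (family, class,
clade), label names sorted lexicographically within each block.  Every
instance carries exactly one active label per block, so the vector is a
concatenation of block-wise one-hots; rank blocks act as auxiliary
supervision while reported metrics are computed on the host slice.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

_RANK_ORDER = ("family", "class", "clade")


@dataclass(frozen=True)
class LabelCatalogue:
    """Ordered label space: position -> (rank, label-name)."""

    entries: tuple[tuple[str, str], ...]

    @property
    def C(self) -> int:
        return len(self.entries)

    @property
    def ranks(self) -> tuple[str, ...]:
        seen = []
        for rank, _ in self.entries:
            if rank not in seen:
                seen.append(rank)
        return tuple(seen)

    def block(self, rank: str) -> slice:
        idx = [i for i, (r, _) in enumerate(self.entries) if r == rank]
        if not idx:
            raise KeyError(f"no {rank!r} block in catalogue")
        return slice(idx[0], idx[-1] + 1)

    def block_labels(self, rank: str) -> list[str]:
        return [name for r, name in self.entries if r == rank]

    def position(self, rank: str, name: str) -> int:
        try:
            return self.entries.index((rank, name))
        except ValueError:
            raise KeyError(f"unknown {rank} label {name!r}") from None

    def column_names(self) -> list[str]:
        return [f"{rank}:{name}" for rank, name in self.entries]

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump([list(e) for e in self.entries], fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "LabelCatalogue":
        with open(path) as fh:
            return cls(tuple((r, n) for r, n in json.load(fh)))


def build_label_space(label_table: pd.DataFrame, rank_selection=()) -> LabelCatalogue:
    """Host block plus one block per selected rank, 1 or 2 ranks at most.

    Selecting more than two ranks is allowed but warned against: joint
    training over three or more rank blocks tends to overfit.
    """
    ranks = [r for r in _RANK_ORDER if r in rank_selection]
    unknown = set(rank_selection) - set(_RANK_ORDER)
    if unknown:
        raise ValueError(f"unknown ranks: {sorted(unknown)}")
    if len(ranks) > 2:
        warnings.warn(
            "selecting more than two rank labels tends to overfit; proceeding anyway"
        )
    entries = [("host", h) for h in sorted(label_table["host"].unique())]
    for rank in ranks:
        if rank not in label_table.columns:
            raise ValueError(f"label table has no {rank!r} column")
        entries += [(rank, name) for name in sorted(label_table[rank].unique())]
    return LabelCatalogue(tuple(entries))


@dataclass(frozen=True)
class MultilabelTarget:
    instance_id: str
    O: np.ndarray
    catalogue: LabelCatalogue


def binarize(instance_labels: dict[str, str], catalogue: LabelCatalogue,
             instance_id: str = "") -> MultilabelTarget:
    """One-hot each block: exactly one 1 per constituent rank."""
    vec = np.zeros(catalogue.C, dtype=int)
    for rank in catalogue.ranks:
        if rank not in instance_labels:
            raise ValueError(f"instance {instance_id!r} missing a {rank!r} label")
        vec[catalogue.position(rank, instance_labels[rank])] = 1
    return MultilabelTarget(instance_id, vec, catalogue)


def binarize_table(label_table: pd.DataFrame, catalogue: LabelCatalogue) -> np.ndarray:
    """Binarize every row of a label table into an (N, C) matrix."""
    out = np.zeros((len(label_table), catalogue.C), dtype=int)
    for i, (_, row) in enumerate(label_table.iterrows()):
        out[i] = binarize(row.to_dict(), catalogue, str(row.get("id", i))).O
    return out


def decode_target(O: np.ndarray, catalogue: LabelCatalogue) -> dict[str, str]:
    """Inverse of :func:`binarize` for block-wise one-hot vectors."""
    labels = {}
    for rank in catalogue.ranks:
        blk = catalogue.block(rank)
        block = np.asarray(O)[blk]
        if block.sum() != 1:
            raise ValueError(f"{rank} block is not one-hot: {block}")
        labels[rank] = catalogue.block_labels(rank)[int(np.argmax(block))]
    return labels


def host_slice(predictions: np.ndarray, catalogue: LabelCatalogue
               ) -> tuple[np.ndarray, list[str]]:
    """Extract the host columns and decode hard host predictions.

    Returns the host-score submatrix and, per row, the argmax host name
    (ties broken toward the lowest index, deterministically).
    """
    blk = catalogue.block("host")
    hosts = catalogue.block_labels("host")
    sub = np.atleast_2d(np.asarray(predictions, float))[:, blk]
    picked = [hosts[int(np.argmax(row))] for row in sub]
    return sub, picked
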