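"""Macroevolutionary lag between paired chronograms.

Given a dated nematocyst-protein tree and a dated organismal tree, each
mapped clade contributes an age offset lag = age_A - age_B (positive when the
nematocyst node is older).  Clades are matched by shared leaf set (robust to
label drift between gene and species trees) or by internal-node label; a leaf
set that is not monophyletic in a tree is computed on its MRCA and flagged
rather than rejected, since gene trees are often topologically incongruent
with the species tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import DataValidationError
from .io import Chronogram, _open_text


@dataclass(frozen=True)
class CladeLag:
    label: str
    age_a: float
    age_b: float
    lag: float
    monophyletic_a: bool = True
    monophyletic_b: bool = True

    def to_dict(self) -> dict:
        return {
            "clade": self.label,
            "age_a": self.age_a,
            "age_b": self.age_b,
            "lag": self.lag,
            "monophyletic_a": self.monophyletic_a,
            "monophyletic_b": self.monophyletic_b,
        }


@dataclass(frozen=True)
class LagReport:
    """Per-clade age offsets plus min/max/mean summary."""

    clades: tuple[CladeLag, ...]

    @property
    def min_lag(self) -> float:
        return min(c.lag for c in self.clades)

    @property
    def max_lag(self) -> float:
        return max(c.lag for c in self.clades)

    @property
    def mean_lag(self) -> float:
        return sum(c.lag for c in self.clades) / len(self.clades)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.to_dict() for c in self.clades])

    def summary(self) -> str:
        lines = [
            "Macroevolutionary lag (tree A ages minus tree B ages, My)",
            "-" * 60,
        ]
        for c in self.clades:
            note = "" if (c.monophyletic_a and c.monophyletic_b) else "  [non-monophyletic]"
            lines.append(
                f"{c.label:<16} A {c.age_a:8.2f}  B {c.age_b:8.2f}  lag {c.lag:+8.2f}{note}"
            )
        lines.append(
            f"lag range [{self.min_lag:.2f}, {self.max_lag:.2f}] My, mean {self.mean_lag:.2f} My"
        )
        return "\n".join(lines)


def node_age(tree: Chronogram, leaf_set: Iterable[str]) -> float:
    """Age (My) of the MRCA of ``leaf_set`` in a chronogram."""
    return tree.node_age(leaf_set)


def read_clade_map(source) -> list[tuple[str, frozenset, frozenset]]:
    """Read a clade-map TSV: clade_label, comma-separated leaves in A and in B."""
    fh, close = _open_text(source)
    try:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    finally:
        if close:
            fh.close()
    for col in ("clade_label", "leaves_a", "leaves_b"):
        if col not in df.columns:
            raise DataValidationError(f"clade map missing column {col!r}")
    out = []
    for rec in df.itertuples(index=False):
        la = frozenset(x for x in rec.leaves_a.split(",") if x)
        lb = frozenset(x for x in rec.leaves_b.split(",") if x)
        if not la or not lb:
            raise DataValidationError(f"clade {rec.clade_label!r}: empty leaf set")
        out.append((rec.clade_label, la, lb))
    return out


def write_clade_map(clades: Sequence, dest) -> None:
    fh, close = _open_text(dest, "wt")
    try:
        fh.write("clade_label\tleaves_a\tleaves_b\n")
        for c in clades:
            label, la, lb = (c.label, c.leaves_a, c.leaves_b) if hasattr(c, "label") else c
            fh.write(f"{label}\t{','.join(sorted(la))}\t{','.join(sorted(lb))}\n")
    finally:
        if close:
            fh.close()


def build_clade_map(
    tree_a: Chronogram, tree_b: Chronogram, mode: str = "by_leafset"
) -> list[tuple[str, frozenset, frozenset]]:
    """Pair internal nodes of two chronograms automatically.

    ``by_leafset`` pairs nodes with identical leaf sets; ``by_label`` pairs
    named internal nodes by label (leaf sets then come from each tree's node).
    """
    if mode == "by_leafset":
        clades_a = tree_a.internal_clades()
        clades_b = tree_b.internal_clades()
        shared = sorted(
            set(clades_a) & set(clades_b), key=lambda s: (-len(s), sorted(s))
        )
        return [(f"clade_{i + 1}", s, s) for i, s in enumerate(shared)]
    if mode == "by_label":
        def _named(tree):
            out = {}
            for node in tree.tree.preorder_internal_node_iter():
                label = node.label or (node.taxon.label if node.taxon else None)
                if label:
                    out[label] = tree.clade_leafset(node)
            return out

        named_a = _named(tree_a)
        named_b = _named(tree_b)
        return [
            (lab, named_a[lab], named_b[lab]) for lab in sorted(set(named_a) & set(named_b))
        ]
    raise DataValidationError(f"unknown clade-matching mode {mode!r}")


def compute_lag(
    tree_a: Chronogram,
    tree_b: Chronogram,
    clade_map: Sequence | None = None,
) -> LagReport:
    """Per-clade age offsets between two chronograms.

    ``clade_map`` entries are (label, leaves_a, leaves_b) tuples or objects
    with those attributes; when omitted, clades are paired by shared leaf set.
    Lag > 0 means the tree-A (nematocyst) node is older.
    """
    if clade_map is None:
        clade_map = build_clade_map(tree_a, tree_b)
    if len(clade_map) == 0:
        raise DataValidationError("no mappable clades between the two trees")
    out = []
    for entry in clade_map:
        if hasattr(entry, "label"):
            label, la, lb = entry.label, entry.leaves_a, entry.leaves_b
        else:
            label, la, lb = entry
        node_a = tree_a.mrca(la)
        node_b = tree_b.mrca(lb)
        mono_a = tree_a.clade_leafset(node_a) == frozenset(la)
        mono_b = tree_b.clade_leafset(node_b) == frozenset(lb)
        age_a = node_a.age_my
        age_b = node_b.age_my
        out.append(
            CladeLag(
                label=label,
                age_a=age_a,
                age_b=age_b,
                lag=age_a - age_b,
                monophyletic_a=mono_a,
                monophyletic_b=mono_b,
            )
        )
    return LagReport(clades=tuple(out))
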