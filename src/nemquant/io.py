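"""Canonical gene-statistics table, HyPhy result adapters, and dated trees.

The pipeline's unit of data is one ortholog's selection summary: a nematocyst
classification (NEM / NONNEM / UNKNOWN), a gene-wide BUSTED p-value, the
per-branch proportions of codons in positively selected rate classes from
aBSREL, and dN / dS from a codon-model fit.  Tables travel as UTF-8
tab-separated text ("." decimal, "NA" for missing, no quoting); readers
accept plain or gzip-compressed files.  Dated trees are Newick with branch
lengths in millions of years.
"""

from __future__ import annotations

import gzip
import io as _io
import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import AdapterError, DataValidationError

NEM_STATUSES = ("NEM", "NONNEM", "UNKNOWN")

#: canonical column order of the gene-statistics TSV
GENE_STATS_COLUMNS = (
    "gene_id",
    "nem_status",
    "busted_p",
    "dn",
    "ds",
    "branch_sel_prop",
    "go_terms",
)


def _open_text(source, mode: str = "rt"):
    """Open a path as text, transparently handling gzip; pass file objects through."""
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8"), True
    if "r" in mode and path.exists():
        with open(path, "rb") as fh:
            if fh.read(2) == b"\x1f\x8b":
                return gzip.open(path, mode, encoding="utf-8"), True
    return open(path, mode, encoding="utf-8"), True


def _fmt(x: float) -> str:
    """Shortest round-tripping decimal representation."""
    return repr(float(x))


# ---------------------------------------------------------------------------
# gene statistics table
# ---------------------------------------------------------------------------

def validate_gene_stats(df: pd.DataFrame) -> pd.DataFrame:
    """Check the invariants of a gene-statistics frame, returning it unchanged.

    Raises :class:`DataValidationError` naming the first offending row/column.
    """
    for col in GENE_STATS_COLUMNS:
        if col not in df.columns:
            raise DataValidationError(f"missing required column {col!r}")
    dup = df["gene_id"].duplicated()
    if dup.any():
        gid = df.loc[dup, "gene_id"].iloc[0]
        raise DataValidationError(f"duplicate gene_id {gid!r}")
    for row, rec in enumerate(df.itertuples(index=False)):
        if rec.nem_status not in NEM_STATUSES:
            raise DataValidationError(
                f"row {row}, column 'nem_status': {rec.nem_status!r} not in {NEM_STATUSES}"
            )
        if not (0.0 <= rec.busted_p <= 1.0):
            raise DataValidationError(
                f"row {row}, column 'busted_p': {rec.busted_p} outside [0, 1]"
            )
        if rec.dn < 0 or rec.ds < 0:
            raise DataValidationError(f"row {row}: dn/ds must be nonnegative")
        props = np.asarray(rec.branch_sel_prop, dtype=float)
        if props.size and (props.min() < 0 or props.max() > 1):
            raise DataValidationError(
                f"row {row}, column 'branch_sel_prop': proportion outside [0, 1]"
            )
    return df


def read_gene_stats(source) -> pd.DataFrame:
    """Read a gene-statistics TSV into a validated DataFrame.

    ``branch_sel_prop`` holds a float ndarray per row, ``go_terms`` a frozenset
    of category identifiers.  Row order is preserved.
    """
    fh, close = _open_text(source)
    try:
        raw = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    finally:
        if close:
            fh.close()
    for col in GENE_STATS_COLUMNS:
        if col not in raw.columns:
            raise DataValidationError(f"missing required column {col!r}")

    def _float(row: int, col: str, text: str) -> float:
        try:
            return float(text)
        except ValueError:
            raise DataValidationError(
                f"row {row}, column {col!r}: unparsable number {text!r}"
            ) from None

    records = {c: [] for c in GENE_STATS_COLUMNS}
    for row, rec in enumerate(raw.itertuples(index=False)):
        records["gene_id"].append(rec.gene_id)
        records["nem_status"].append(rec.nem_status)
        records["busted_p"].append(_float(row, "busted_p", rec.busted_p))
        records["dn"].append(_float(row, "dn", rec.dn))
        records["ds"].append(_float(row, "ds", rec.ds))
        if rec.branch_sel_prop:
            props = np.array(
                [_float(row, "branch_sel_prop", t) for t in rec.branch_sel_prop.split(";")]
            )
        else:
            props = np.empty(0)
        records["branch_sel_prop"].append(props)
        terms = frozenset(t for t in rec.go_terms.split("|") if t)
        records["go_terms"].append(terms)
    df = pd.DataFrame(records, columns=list(GENE_STATS_COLUMNS))
    return validate_gene_stats(df)


def write_gene_stats(df: pd.DataFrame, dest) -> None:
    """Write a gene-statistics frame as canonical TSV (round-trips exactly)."""
    validate_gene_stats(df)
    fh, close = _open_text(dest, "wt")
    try:
        fh.write("\t".join(GENE_STATS_COLUMNS) + "\n")
        for rec in df.itertuples(index=False):
            props = ";".join(_fmt(p) for p in np.asarray(rec.branch_sel_prop, dtype=float))
            terms = "|".join(sorted(rec.go_terms))
            fh.write(
                f"{rec.gene_id}\t{rec.nem_status}\t{_fmt(rec.busted_p)}\t"
                f"{_fmt(rec.dn)}\t{_fmt(rec.ds)}\t{props}\t{terms}\n"
            )
    finally:
        if close:
            fh.close()


def omega(df: pd.DataFrame) -> pd.Series:
    """dN/dS per gene; NaN where dS = 0 (omega undefined)."""
    ds = df["ds"].to_numpy(dtype=float)
    dn = df["dn"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(ds > 0, dn / np.where(ds > 0, ds, 1.0), np.nan)
    return pd.Series(w, index=df.index, name="omega")


# ---------------------------------------------------------------------------
# HyPhy adapters
# ---------------------------------------------------------------------------

def _load_json(document) -> tuple[dict, str]:
    if isinstance(document, Mapping):
        return dict(document), "<dict>"
    fh, close = _open_text(document)
    name = getattr(fh, "name", str(document))
    try:
        try:
            return json.load(fh), name
        except json.JSONDecodeError as exc:
            raise AdapterError(f"{name}: malformed JSON ({exc})") from None
    finally:
        if close:
            fh.close()


def parse_busted_json(document) -> tuple[str, float]:
    """Extract (gene_id, gene-wide p-value) from a HyPhy BUSTED result.

    Extra fields are tolerated (HyPhy versions drift); an absent p-value is an
    :class:`AdapterError` identifying the file.
    """
    doc, name = _load_json(document)
    try:
        p = float(doc["test results"]["p-value"])
    except (KeyError, TypeError, ValueError):
        raise AdapterError(f"{name}: no test-results p-value field") from None
    gene_id = str(doc.get("input", {}).get("file name", name))
    if not (0.0 <= p <= 1.0):
        raise AdapterError(f"{name}: p-value {p} outside [0, 1]")
    return gene_id, p


def parse_absrel_json(
    document, *, only_significant: bool = False, p_cutoff: float = 0.05
) -> tuple[str, np.ndarray]:
    """Extract per-branch proportions of selected codons from a HyPhy aBSREL result.

    A branch's proportion is the summed weight of its maximum-likelihood rate
    classes with omega > 1, for *all* branches by default (the downstream
    statistic averages along all branches).  With ``only_significant=True``,
    branches whose corrected p-value exceeds ``p_cutoff`` are zeroed instead.
    Branches are ordered by name so vectors are comparable across genes.
    """
    doc, name = _load_json(document)
    try:
        attrs = doc["branch attributes"]["0"]
    except (KeyError, TypeError):
        raise AdapterError(f"{name}: no branch attributes") from None
    gene_id = str(doc.get("input", {}).get("file name", name))
    props = []
    for branch in sorted(attrs):
        info = attrs[branch]
        dist = info.get("Rate Distributions")
        if dist is None:
            raise AdapterError(f"{name}: branch {branch!r} has no rate distributions")
        weights = [float(w) for _, w in dist]
        if abs(sum(weights) - 1.0) > 1e-6:
            raise AdapterError(
                f"{name}: branch {branch!r} rate-class weights sum to {sum(weights)!r}, not 1"
            )
        prop = sum(w for om, w in dist if float(om) > 1.0)
        if only_significant and float(info.get("Corrected P-value", 1.0)) > p_cutoff:
            prop = 0.0
        props.append(min(max(prop, 0.0), 1.0))
    return gene_id, np.asarray(props, dtype=float)


# ---------------------------------------------------------------------------
# dated trees
# ---------------------------------------------------------------------------

class Chronogram:
    """A rooted ultrametric tree with node ages in millions of years.

    Age is height above the present: leaves are at 0 (within a relative
    tolerance), the root is oldest, and a parent is never younger than a child.
    """

    def __init__(self, tree: dendropy.Tree, tolerance: float = 1e-6):
        tree.is_rooted = True  # ages are defined on rooted trees only
        self.tree = tree
        self.tolerance = tolerance
        self._compute_ages()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, source, tolerance: float = 1e-6) -> "Chronogram":
        """Read a dated Newick file (branch lengths in My); paths may be gzipped."""
        if isinstance(source, str) and source.lstrip().startswith("("):
            text = source
        else:
            fh, close = _open_text(source)
            try:
                text = fh.read()
            finally:
                if close:
                    fh.close()
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False
        )
        return cls(tree, tolerance=tolerance)

    def _compute_ages(self) -> None:
        tree = self.tree
        depths: dict[int, float] = {}
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            length = node.edge.length or 0.0
            depths[id(node)] = (depths[id(parent)] if parent else 0.0) + length
        leaf_depths = {
            (n.taxon.label if n.taxon else str(n)): depths[id(n)]
            for n in tree.leaf_node_iter()
        }
        height = max(leaf_depths.values())
        tol = self.tolerance * max(height, 1.0)
        worst = max(leaf_depths, key=lambda k: abs(leaf_depths[k] - height))
        if abs(leaf_depths[worst] - height) > tol:
            raise DataValidationError(
                "tree is not ultrametric: leaf "
                f"{worst!r} has root distance {leaf_depths[worst]:g} vs height {height:g}"
            )
        self.height = height
        self._ages = {id(n): height - d for n, d in ((m, depths[id(m)]) for m in tree)}
        for node in tree:
            node.age_my = self._ages[id(node)]

    # -- queries ------------------------------------------------------------

    @property
    def root_age(self) -> float:
        return self._ages[id(self.tree.seed_node)]

    @property
    def leaf_labels(self) -> frozenset[str]:
        return frozenset(t.label for t in self.tree.taxon_namespace)

    def mrca(self, leaf_set: Iterable[str]) -> dendropy.Node:
        labels = sorted(set(leaf_set))
        unknown = set(labels) - self.leaf_labels
        if unknown:
            raise DataValidationError(f"unknown leaf label(s): {sorted(unknown)}")
        if len(labels) == 1:
            for leaf in self.tree.leaf_node_iter():
                if leaf.taxon and leaf.taxon.label == labels[0]:
                    return leaf
        node = self.tree.mrca(taxon_labels=labels)
        if node is None:
            raise DataValidationError(f"no MRCA found for {labels}")
        return node

    def node_age(self, leaf_set: Iterable[str]) -> float:
        """Age (My) of the most recent common ancestor of ``leaf_set``."""
        return self._ages[id(self.mrca(leaf_set))]

    def clade_leafset(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(l.taxon.label for l in node.leaf_iter())

    def internal_clades(self) -> dict[frozenset[str], float]:
        """Map each internal node's leaf set to its age."""
        out = {}
        for node in self.tree.preorder_internal_node_iter():
            out[self.clade_leafset(node)] = self._ages[id(node)]
        return out

    # -- output -------------------------------------------------------------

    def as_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip() + "\n"

    def write_newick(self, dest) -> None:
        fh, close = _open_text(dest, "wt")
        try:
            fh.write(self.as_newick())
        finally:
            if close:
                fh.close()


def read_dated_newick(source, tolerance: float = 1e-6) -> Chronogram:
    """Read an r8s-style dated Newick tree into a :class:`Chronogram`."""
    return Chronogram.from_newick(source, tolerance=tolerance)
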