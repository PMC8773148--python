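"""NEM/non-NEM classification from similarity evidence, and ortholog set arithmetic.

Genes are labelled NEM when their best hit against a nematocyst-proteome
repertory reaches an e-value cutoff (default 1e-5); genes absent from the
similarity table are non-NEM.  Ortholog-family comparisons across species are
reported both as a core set (shared by every species) and as UpSet-style
exclusive intersection regions, with pairwise (Venn-style) overlaps available
because prose "shared" counts are ambiguous between the two conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd

from .errors import DataValidationError
from .io import _open_text

DEFAULT_EVALUE_CUTOFF = 1e-5


def classify_genes(
    similarity: pd.DataFrame,
    gene_ids: Iterable[str],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> dict[str, str]:
    """Label every gene in ``gene_ids`` as NEM or NONNEM.

    ``similarity`` has columns gene_id and best_evalue; a gene is NEM iff its
    best e-value is <= the cutoff.  Genes absent from the table are NONNEM.
    Classification is monotone in the cutoff: raising it never removes a gene
    from the NEM class.
    """
    if evalue_cutoff <= 0:
        raise DataValidationError("evalue_cutoff must be positive")
    if similarity["gene_id"].duplicated().any():
        dup = similarity.loc[similarity["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise DataValidationError(f"duplicate gene_id {dup!r} in similarity table")
    if (similarity["best_evalue"] <= 0).any():
        raise DataValidationError("e-values must be positive")
    best = dict(zip(similarity["gene_id"], similarity["best_evalue"]))
    return {
        g: "NEM" if best.get(g, float("inf")) <= evalue_cutoff else "NONNEM"
        for g in gene_ids
    }


# ---------------------------------------------------------------------------
# ortholog families
# ---------------------------------------------------------------------------

def read_family(source) -> dict[str, set[str]]:
    """Read a (species_id, og_id) TSV into per-species ortholog-group sets."""
    fh, close = _open_text(source)
    try:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    finally:
        if close:
            fh.close()
    for col in ("species_id", "og_id"):
        if col not in df.columns:
            raise DataValidationError(f"family table missing column {col!r}")
    family: dict[str, set[str]] = {}
    for rec in df.itertuples(index=False):
        family.setdefault(rec.species_id, set()).add(rec.og_id)
    return family


def core_set(family: Mapping[str, set]) -> set:
    """Ortholog groups present in every species (the core set)."""
    if len(family) == 0:
        raise DataValidationError("empty ortholog family")
    if len(family) < 2:
        raise DataValidationError("core set needs >= 2 species")
    sets = list(family.values())
    return set.intersection(*(set(s) for s in sets))


@dataclass
class IntersectionProfile:
    """UpSet-style exclusive intersection regions of an ortholog family.

    ``exclusive`` maps each nonempty species subset to the count of elements
    belonging to exactly that subset; counts sum to the union's cardinality.
    """

    species: tuple[str, ...]
    exclusive: dict[frozenset, int]
    members: dict[frozenset, set] = field(repr=False, default_factory=dict)

    @property
    def union_size(self) -> int:
        return sum(self.exclusive.values())

    def pairwise_overlaps(self) -> dict[frozenset, int]:
        """Venn-style total overlap |A intersect B| for every species pair."""
        out = {}
        for a, b in combinations(self.species, 2):
            key = frozenset((a, b))
            out[key] = sum(
                c for sub, c in self.exclusive.items() if key <= sub
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subset": "&".join(sorted(sub)), "degree": len(sub), "count": c}
            for sub, c in sorted(
                self.exclusive.items(), key=lambda kv: (-kv[1], sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows, columns=["subset", "degree", "count"])


def intersection_profile(
    family: Mapping[str, set], keep_members: bool = False
) -> IntersectionProfile:
    """Assign every element of the union to its exclusive species subset."""
    if len(family) < 2:
        raise DataValidationError("intersection profile needs >= 2 species")
    if len(family) > 16:
        raise DataValidationError(
            f"{len(family)} species: exclusive regions are only enumerable up to "
            "16 species; restrict the family first"
        )
    species = tuple(sorted(family))
    exclusive: dict[frozenset, int] = {}
    members: dict[frozenset, set] = {}
    union = set().union(*(set(family[s]) for s in species))
    for element in union:
        sub = frozenset(s for s in species if element in family[s])
        exclusive[sub] = exclusive.get(sub, 0) + 1
        if keep_members:
            members.setdefault(sub, set()).add(element)
    return IntersectionProfile(species=species, exclusive=exclusive, members=members)
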