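"""Discrete trait matrices and codebooks for cross-cultural data.

A trait matrix holds per-society category codes for a set of discrete
variables (e.g. Ethnographic Atlas style codings: roofing materials,
marriage payments, class stratification, ...).  Each variable carries
codebook metadata: a category count, an ecological-vs-social class label,
and optionally a recode map collapsing database categories into
ethnographically meaningful ones (e.g. typed slavery categories into
present/absent).

Category codes are treated as nominal throughout the package: parsimony
uses unit change costs and the Markov model is symmetric, so only state
identity matters, never ordering.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, replace
from typing import IO, Iterable, Mapping

import pandas as pd

logger = logging.getLogger("traitrates")

__all__ = [
    "MISSING",
    "TraitDataError",
    "UnanalysableTrait",
    "TraitVariable",
    "TraitMatrix",
    "load_trait_matrix",
    "recode_variable",
    "trait_coverage",
    "parse_recode_string",
]

#: Sentinel stored for societies the source database could not code.
MISSING = None

CLASS_LABELS = ("eco", "social")


class TraitDataError(ValueError):
    """Raised for invalid trait tables or codebooks."""


class UnanalysableTrait(ValueError):
    """A trait with too little data (or variation) to place on a tree."""


@dataclass(frozen=True)
class TraitVariable:
    """One discrete variable: codebook metadata plus per-society states.

    ``states`` maps every society to an integer code in
    ``[1, n_categories]`` or to :data:`MISSING`.  ``n_categories`` is the
    codebook's category count, which may exceed the number of states
    actually observed; the two play different roles downstream (the
    codebook count is a statistical covariate, the observed count sets the
    Markov state space).
    """

    id: str
    description: str
    n_categories: int
    trait_class: str
    states: Mapping[str, int | None]

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise TraitDataError(
                f"variable {self.id}: n_categories must be >= 2, got {self.n_categories}"
            )
        if self.trait_class not in CLASS_LABELS:
            raise TraitDataError(
                f"variable {self.id}: class must be one of {CLASS_LABELS}, "
                f"got {self.trait_class!r}"
            )
        for society, code in self.states.items():
            if code is MISSING:
                continue
            if not isinstance(code, int) or not 1 <= code <= self.n_categories:
                raise TraitDataError(
                    f"variable {self.id}: state {code!r} for {society!r} outside "
                    f"[1, {self.n_categories}]"
                )

    def coded_states(self) -> dict[str, int]:
        """Society -> code, restricted to coded (non-missing) societies."""
        return {s: c for s, c in self.states.items() if c is not MISSING}


@dataclass(frozen=True)
class TraitMatrix:
    """All variables for one family of societies."""

    family: str
    societies: list[str]
    variables: list[TraitVariable]

    def __post_init__(self) -> None:
        if not self.variables:
            raise TraitDataError("trait matrix with no variables")
        roster = set(self.societies)
        for v in self.variables:
            extra = set(v.states) - roster
            if extra:
                raise TraitDataError(
                    f"variable {v.id}: states for societies outside the roster: "
                    f"{sorted(extra)[:5]}"
                )

    def __getitem__(self, variable_id: str) -> TraitVariable:
        for v in self.variables:
            if v.id == variable_id:
                return v
        raise KeyError(variable_id)


def trait_coverage(v: TraitVariable) -> tuple[set[str], int, int]:
    """Return (coded society set, N, number of distinct observed states).

    N — the number of societies with a non-missing code — varies by trait
    because database coders leave states blank when the ethnographic record
    is insufficient; it is carried into the statistics as a covariate since
    more taxa allow more inferable changes.
    """
    coded = {s for s, c in v.states.items() if c is not MISSING}
    observed = {v.states[s] for s in coded}
    return coded, len(coded), len(observed)


def recode_variable(
    v: TraitVariable, recode_map: Mapping[int, int]
) -> TraitVariable:
    """Collapse or relabel categories; missing entries stay missing.

    The map must cover every observed non-missing code, and the target
    codes must form a contiguous range starting at 1 (the new category
    count is the number of distinct target codes).  Typical use: a
    database variable whose typed categories encode coder uncertainty is
    collapsed to presence/absence.
    """
    observed = {c for c in v.states.values() if c is not MISSING}
    unmapped = observed - set(recode_map)
    if unmapped:
        raise TraitDataError(
            f"variable {v.id}: recode map misses observed codes {sorted(unmapped)}"
        )
    targets = sorted(set(recode_map.values()))
    if targets != list(range(1, len(targets) + 1)):
        raise TraitDataError(
            f"variable {v.id}: recode targets {targets} are not contiguous from 1"
        )
    new_states = {
        s: (MISSING if c is MISSING else recode_map[c]) for s, c in v.states.items()
    }
    # A map collapsing everything onto one code yields a constant variable;
    # keep n_categories at the minimum legal 2 and let coverage/variation
    # checks flag it un-analysable downstream.
    return replace(v, n_categories=max(len(targets), 2), states=new_states)


def parse_recode_string(text: str) -> dict[int, int]:
    """Parse ``"old1:new1;old2:new2;..."`` into a recode map."""
    out: dict[int, int] = {}
    for item in text.split(";"):
        item = item.strip()
        if not item:
            continue
        old, _, new = item.partition(":")
        out[int(old)] = int(new)
    if not out:
        raise TraitDataError(f"empty recode string {text!r}")
    return out


def load_codebook(source: str | os.PathLike | IO[str]) -> pd.DataFrame:
    """Read a codebook CSV: id, description, n_categories, class[, recode]."""
    cb = pd.read_csv(source, dtype=str)
    required = {"id", "description", "n_categories", "class"}
    missing_cols = required - set(cb.columns)
    if missing_cols:
        raise TraitDataError(f"codebook missing columns {sorted(missing_cols)}")
    cb["n_categories"] = cb["n_categories"].astype(int)
    bad = ~cb["class"].isin(CLASS_LABELS)
    if bad.any():
        raise TraitDataError(
            f"codebook class labels must be in {CLASS_LABELS}; "
            f"got {sorted(cb.loc[bad, 'class'].unique())}"
        )
    return cb


def load_trait_matrix(
    table: str | os.PathLike | IO[str],
    codebook: str | os.PathLike | IO[str] | pd.DataFrame,
    missing_code: str = "?",
    tree_taxa: Iterable[str] | None = None,
    family: str = "",
    society_column: str = "society",
    apply_recode: bool = True,
) -> TraitMatrix:
    """Load a society x variable CSV, validated against its codebook.

    Every variable column must appear in the codebook; states are checked
    against the codebook category count.  Societies absent from
    ``tree_taxa`` (when given) are dropped with a logged warning — they
    cannot be placed on the phylogeny.  Codebook recode maps, when present
    and ``apply_recode`` is set, are applied after validation.
    """
    cb = codebook if isinstance(codebook, pd.DataFrame) else load_codebook(codebook)
    cb = cb.set_index("id", drop=False)
    df = pd.read_csv(table, dtype=str)
    if society_column not in df.columns:
        raise TraitDataError(f"trait table has no {society_column!r} column")
    societies = df[society_column].tolist()
    if len(set(societies)) != len(societies):
        raise TraitDataError("duplicate society ids in trait table")

    if tree_taxa is not None:
        taxa = set(tree_taxa)
        dropped = [s for s in societies if s not in taxa]
        if dropped:
            logger.warning(
                "family %s: dropping %d societies absent from the tree sample: %s",
                family, len(dropped), dropped[:5],
            )
            df = df[df[society_column].isin(taxa)]
            societies = df[society_column].tolist()

    variables: list[TraitVariable] = []
    for col in df.columns:
        if col == society_column:
            continue
        if col not in cb.index:
            raise TraitDataError(f"variable {col!r} not in codebook")
        row = cb.loc[col]
        states: dict[str, int | None] = {}
        for society, raw in zip(societies, df[col]):
            if pd.isna(raw) or str(raw).strip() == missing_code:
                states[society] = MISSING
                continue
            try:
                code = int(str(raw).strip())
            except ValueError as exc:
                raise TraitDataError(
                    f"variable {col}: non-integer state {raw!r} for {society!r}"
                ) from exc
            states[society] = code
        v = TraitVariable(
            id=str(row["id"]),
            description=str(row["description"]),
            n_categories=int(row["n_categories"]),
            trait_class=str(row["class"]),
            states=states,
        )
        if apply_recode and "recode" in cb.columns and isinstance(row.get("recode"), str):
            recode_text = row["recode"].strip()
            if recode_text:
                v = recode_variable(v, parse_recode_string(recode_text))
        variables.append(v)
    return TraitMatrix(family=family, societies=societies, variables=variables)
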