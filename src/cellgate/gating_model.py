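"""Hierarchical gating models: signed marker signatures arranged in levels.

A gating model mimics a flow-cytometry gating strategy: each level filters
the cells that passed the previous one. Within a level, *positive*
signatures describe alternative identities of the target population (a
cell needs any one of them) while *negative* signatures veto (any one
above threshold excludes the cell). Inside a signature, an individual
gene can itself be negated with a trailing "-" (e.g. ``CD3D-``); negated
genes act at the scoring stage by subtracting their own rank score, which
is distinct from whole ``use_as=negative`` signatures that are
thresholded separately by the gating engine.

Models are stored as tab-separated text with columns
``levels, use_as, name, signature``::

    levels  use_as    name        signature
    level1  positive  immune      PTPRC
    level2  positive  macrophage  CD68;FCGR1A
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SignedGene",
    "Signature",
    "GatingLevel",
    "GatingModel",
    "parse_gene_token",
    "parse_gating_table",
    "serialize_gating_table",
    "build_model",
    "load_model_db",
    "validate_against_features",
    "ValidationReport",
]

REQUIRED_COLUMNS = ("levels", "use_as", "name", "signature")
_LEVEL_RE = re.compile(r"^level(\d+)$", re.IGNORECASE)


@dataclass(frozen=True)
class SignedGene:
    """A feature symbol with a sign: +1 supports, -1 opposes."""

    symbol: str
    sign: int = 1

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("empty gene symbol")
        if self.symbol.endswith("-"):
            raise ValueError(
                f"symbol {self.symbol!r} retains a trailing '-'; "
                "parse tokens with parse_gene_token"
            )
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")

    def to_token(self) -> str:
        return self.symbol + ("-" if self.sign < 0 else "")


def parse_gene_token(token: str) -> SignedGene:
    """Parse "CD3D-" -> SignedGene("CD3D", -1); "PTPRC" -> +1."""
    token = token.strip()
    if token.endswith("-"):
        return SignedGene(symbol=token[:-1].strip(), sign=-1)
    return SignedGene(symbol=token, sign=1)


@dataclass
class Signature:
    """A named, ordered set of signed marker genes.

    At least one gene must be positive: a signature of only negated
    genes has nothing to score for.
    """

    name: str
    genes: list

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("signature needs a name")
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")
        if not any(g.sign > 0 for g in self.genes):
            raise ValueError(
                f"signature {self.name!r} contains only negated genes"
            )

    @property
    def positive_genes(self) -> list:
        return [g for g in self.genes if g.sign > 0]

    @property
    def negative_genes(self) -> list:
        return [g for g in self.genes if g.sign < 0]

    def to_token_string(self) -> str:
        return ";".join(g.to_token() for g in self.genes)


@dataclass
class GatingLevel:
    index: int
    positive_signatures: list
    negative_signatures: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("level index must be >= 1")
        if not self.positive_signatures:
            raise ValueError(
                f"level {self.index} has no positive signatures"
            )

    @property
    def signatures(self) -> list:
        return list(self.positive_signatures) + list(self.negative_signatures)


@dataclass
class GatingModel:
    name: str
    levels: list

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError(f"model {self.name!r} has no levels")
        indices = [lvl.index for lvl in self.levels]
        if indices != list(range(1, len(indices) + 1)):
            raise ValueError(
                f"model {self.name!r}: level indices {indices} are not "
                "consecutive from 1"
            )
        names = [s.name for s in self.signatures]
        if len(names) != len(set(names)):
            raise ValueError(
                f"model {self.name!r}: duplicate signature names"
            )

    @property
    def signatures(self) -> list:
        return [s for lvl in self.levels for s in lvl.signatures]

    @property
    def genes(self) -> list:
        return [g for s in self.signatures for g in s.genes]


# ---------------------------------------------------------------------------
# Parsing / serialization
# ---------------------------------------------------------------------------

def _parse_level_token(token: str) -> int:
    m = _LEVEL_RE.match(str(token).strip())
    if not m:
        raise ValueError(f"bad level value {token!r} (expected 'level<k>')")
    return int(m.group(1))


def _parse_signature_tokens(name: str, raw: str) -> Signature:
    tokens = [t for t in (tok.strip() for tok in str(raw).split(";")) if t]
    if not tokens:
        raise ValueError(f"signature {name!r} has an empty gene list")
    return Signature(name=name, genes=[parse_gene_token(t) for t in tokens])


def _model_from_rows(name: str, rows: pd.DataFrame) -> GatingModel:
    by_level: dict = {}
    for _, row in rows.iterrows():
        idx = _parse_level_token(row["levels"])
        use_as = str(row["use_as"]).strip().lower()
        if use_as not in ("positive", "negative"):
            raise ValueError(
                f"unknown use_as value {row['use_as']!r} "
                "(expected 'positive' or 'negative')"
            )
        sig = _parse_signature_tokens(
            str(row["name"]).strip(), row["signature"]
        )
        pos, neg = by_level.setdefault(idx, ([], []))
        (pos if use_as == "positive" else neg).append(sig)
    indices = sorted(by_level)
    if indices != list(range(1, len(indices) + 1)):
        raise ValueError(
            f"model {name!r}: level numbering {indices} has gaps or does "
            "not start at 1"
        )
    levels = [
        GatingLevel(
            index=i,
            positive_signatures=by_level[i][0],
            negative_signatures=by_level[i][1],
        )
        for i in indices
    ]
    return GatingModel(name=name, levels=levels)


def parse_gating_table(path: os.PathLike | str, name: str | None = None) -> GatingModel:
    """Parse a gating-model TSV; the model name defaults to the file stem."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    if extra:
        warnings.warn(f"{path}: ignoring extra columns {extra}")
    return _model_from_rows(name or path.stem, df[list(REQUIRED_COLUMNS)])


def serialize_gating_table(
    model: GatingModel, path: os.PathLike | str | None = None
) -> str:
    """Canonical TSV form: levels in order, positives before negatives."""
    lines = ["\t".join(REQUIRED_COLUMNS)]
    for lvl in model.levels:
        for use_as, sigs in (
            ("positive", lvl.positive_signatures),
            ("negative", lvl.negative_signatures),
        ):
            for sig in sigs:
                lines.append(
                    f"level{lvl.index}\t{use_as}\t{sig.name}\t"
                    f"{sig.to_token_string()}"
                )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def build_model(name: str, signature: Sequence[str]) -> GatingModel:
    """One-liner constructor: a single-level model from signed gene tokens.

    ``build_model("NK", ["NCAM1", "KLRD1", "CD3D-"])`` yields one level
    with one positive signature named "NK" whose CD3D gene is negated.
    """
    if not signature:
        raise ValueError("signature token list is empty")
    sig = Signature(name=name, genes=[parse_gene_token(t) for t in signature])
    return GatingModel(
        name=name, levels=[GatingLevel(index=1, positive_signatures=[sig])]
    )


def load_model_db(directory: os.PathLike | str) -> dict:
    """Load every ``*.tsv`` gating table in a directory, keyed and iterated
    in sorted model-name order. An unparseable file raises, naming it."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    db: dict = {}
    for path in sorted(directory.glob("*.tsv")):
        try:
            db[path.stem] = parse_gating_table(path)
        except Exception as exc:
            raise ValueError(f"failed to parse model file {path}: {exc}") from exc
    return db


# ---------------------------------------------------------------------------
# Validation against a feature universe
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Which model genes are absent from a feature space.

    ``missing`` maps signature name -> list of absent gene symbols.
    ``unusable`` lists signatures that lost *all* their positive genes;
    a model with any unusable signature cannot be run.
    """

    missing: dict
    unusable: list

    @property
    def usable(self) -> bool:
        return not self.unusable

    @property
    def clean(self) -> bool:
        return not self.missing


def validate_against_features(
    model: GatingModel,
    feature_ids: Iterable[str],
    case_insensitive: bool = False,
) -> ValidationReport:
    """Report model genes absent from ``feature_ids``.

    Matching is exact and case-sensitive after stripping surrounding
    whitespace; pass ``case_insensitive=True`` for a case-folded
    fallback (off by default — silent case-folding can conflate
    distinct gene symbols).
    """
    universe = {str(f).strip() for f in feature_ids}
    if case_insensitive:
        universe = {f.casefold() for f in universe}

    def present(symbol: str) -> bool:
        s = symbol.strip()
        return (s.casefold() if case_insensitive else s) in universe

    missing: dict = {}
    unusable: list = []
    for sig in model.signatures:
        absent = [g.symbol for g in sig.genes if not present(g.symbol)]
        if absent:
            missing[sig.name] = absent
        if not any(present(g.symbol) for g in sig.positive_genes):
            unusable.append(sig.name)
    return ValidationReport(missing=missing, unusable=unusable)
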