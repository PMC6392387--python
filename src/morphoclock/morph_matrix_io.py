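"""Reading, writing and pre-treatment of discrete morphological matrices.

Characters are small-integer coded (``MISSING = -1`` for unknown cells).
Two pre-treatment steps mirror common practice when preparing a published
supermatrix for Mk-model dating:

* tokens scoring a combination of states (``(01)``, ``{0,1}``) are
  collapsed to unknown — partial ambiguity is not propagated;
* characters with more than a maximum number of states (default 10) are
  removed, and the per-character state-space size ``k`` is set either from
  the states observed in the sampled taxa or from external character
  annotations.  The annotated route keeps characters that happen to be
  invariant in the sample, which act like invariable sites and lessen
  ascertainment bias.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .trees import TimeTree, TreeError

__all__ = [
    "MISSING",
    "AmbiguityPolicy",
    "CharacterMatrix",
    "PartitionScheme",
    "MatrixParseError",
    "read_nexus_matrix",
    "write_nexus_matrix",
    "filter_max_states",
    "assign_state_counts",
    "read_newick_tree",
    "write_newick_tree",
    "read_annotations",
    "write_annotations",
    "read_trace_tsv",
    "write_trace_tsv",
    "read_config",
]

log = logging.getLogger(__name__)

MISSING: int = -1

#: NEXUS state symbols in coded order; index = integer state.
SYMBOLS = "0123456789A"


class MatrixParseError(ValueError):
    """Malformed character-matrix input."""


@dataclass(frozen=True)
class AmbiguityPolicy:
    """How non-fundamental tokens are coded.

    ``missing_symbols`` map to MISSING; multi-state tokens (polymorphic or
    uncertain) always map to MISSING as well — the mapping is a pure
    function of the token.
    """

    missing_symbols: tuple[str, ...] = ("?", "-")
    combined_to_missing: bool = True


@dataclass
class CharacterMatrix:
    """Taxa x characters matrix of coded discrete states.

    ``states[i, c]`` is the coded state of taxon ``i`` at character ``c``
    (or MISSING); ``declared_k[c]`` is the size of the state space the
    character is modelled with, which may exceed the number of states seen
    in the sample.
    """

    taxa: list[str]
    states: np.ndarray
    declared_k: np.ndarray
    partition_label: list[str]
    char_id: list[str]

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int16)
        self.declared_k = np.asarray(self.declared_k, dtype=np.int64)
        n_taxa, n_chars = self.states.shape
        if len(self.taxa) != n_taxa:
            raise MatrixParseError("row count does not match taxon count")
        if len(set(self.taxa)) != n_taxa:
            raise MatrixParseError("duplicate taxon labels")
        if not (
            len(self.declared_k) == len(self.partition_label) == len(self.char_id) == n_chars
        ):
            raise MatrixParseError("per-character metadata length mismatch")
        if n_chars and self.declared_k.min() < 2:
            raise MatrixParseError("declared state count below 2")
        bad = (self.states >= self.declared_k[None, :]) & (self.states != MISSING)
        if bad.any():
            c = int(np.argwhere(bad)[0][1])
            raise MatrixParseError(
                f"character {self.char_id[c]}: coded state >= declared k={self.declared_k[c]}"
            )

    @property
    def n_taxa(self) -> int:
        return self.states.shape[0]

    @property
    def n_chars(self) -> int:
        return self.states.shape[1]

    def observed_counts(self) -> np.ndarray:
        """Number of distinct non-missing states per character."""
        out = np.zeros(self.n_chars, dtype=np.int64)
        for c in range(self.n_chars):
            col = self.states[:, c]
            out[c] = len(np.unique(col[col != MISSING]))
        return out

    def select(self, keep: np.ndarray) -> "CharacterMatrix":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return CharacterMatrix(
            list(self.taxa),
            self.states[:, idx],
            self.declared_k[idx],
            [self.partition_label[i] for i in idx],
            [self.char_id[i] for i in idx],
        )


@dataclass(frozen=True)
class PartitionScheme:
    """Disjoint cover of the retained characters by named partitions."""

    name: str
    mapping: dict[str, list[str]]
    kind: str = "anatomical"  # or "unpartitioned"

    def validate(self, matrix: CharacterMatrix) -> None:
        seen: list[str] = []
        for ids in self.mapping.values():
            seen.extend(ids)
        if sorted(seen) != sorted(matrix.char_id):
            raise MatrixParseError(
                f"partition scheme '{self.name}' is not a disjoint cover of the matrix"
            )

    @classmethod
    def unpartitioned(cls, matrix: CharacterMatrix) -> "PartitionScheme":
        return cls("unpartitioned", {"all": list(matrix.char_id)}, kind="unpartitioned")

    @classmethod
    def from_labels(cls, matrix: CharacterMatrix, name: str = "anatomical") -> "PartitionScheme":
        mapping: dict[str, list[str]] = {}
        for cid, lab in zip(matrix.char_id, matrix.partition_label):
            mapping.setdefault(lab, []).append(cid)
        return cls(name, mapping, kind="anatomical")


# ---------------------------------------------------------------------------
# NEXUS matrices


def read_nexus_matrix(path, policy: AmbiguityPolicy | None = None) -> CharacterMatrix:
    """Parse a NEXUS DATA/CHARACTERS block (datatype=standard).

    Ambiguous and polymorphic cells resolve to MISSING per the policy;
    ``declared_k`` is initialised from the observed states (the smallest
    state space containing every coded state, floor 2) and is typically
    overridden by :func:`assign_state_counts`.
    """
    policy = policy or AmbiguityPolicy()
    with open(path) as fh:
        text = fh.read()
    # normalise comma-separated multistate tokens, e.g. {0,1} -> {01}
    text = re.sub(
        r"[({][0-9A?,\s-]*[)}]",
        lambda m: m.group(0).replace(",", "").replace(" ", ""),
        text,
    )
    try:
        dm = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise MatrixParseError(f"cannot parse NEXUS matrix {path}: {exc}") from exc
    taxa = [t.label for t in dm.taxon_namespace]
    if not taxa:
        raise MatrixParseError(f"{path}: empty matrix block")
    rows = []
    lengths = {len(dm[t]) for t in dm.taxon_namespace}
    if len(lengths) != 1:
        raise MatrixParseError(f"{path}: unequal row lengths {sorted(lengths)}")
    n_chars = lengths.pop()
    if n_chars == 0:
        raise MatrixParseError(f"{path}: empty matrix block")
    for t in dm.taxon_namespace:
        row = np.full(n_chars, MISSING, dtype=np.int16)
        for c, cell in enumerate(dm[t]):
            state = getattr(cell, "state_denomination", None)
            symbol = getattr(cell, "symbol", None)
            if symbol in policy.missing_symbols or symbol is None:
                continue
            fundamental = state == dendropy.StateAlphabet.FUNDAMENTAL_STATE
            if not fundamental:
                # polymorphic {..} or uncertain (..) token
                continue
            if symbol not in SYMBOLS:
                raise MatrixParseError(
                    f"{path}: taxon {t.label}, character {c + 1}: "
                    f"undeclared symbol {symbol!r}"
                )
            row[c] = SYMBOLS.index(symbol)
        rows.append(row)
    states = np.vstack(rows)
    declared_k = np.maximum(states.max(axis=0) + 1, 2).astype(np.int64)
    return CharacterMatrix(
        taxa=taxa,
        states=states,
        declared_k=declared_k,
        partition_label=["all"] * n_chars,
        char_id=[f"c{i + 1}" for i in range(n_chars)],
    )


def write_nexus_matrix(matrix: CharacterMatrix, path) -> None:
    """Write a NEXUS DATA block (datatype=standard, symbols 0-9A)."""
    kmax = int(matrix.declared_k.max(initial=2))
    symbols = SYMBOLS[: max(kmax, int(matrix.states.max(initial=1)) + 1)]
    width = max(len(t) for t in matrix.taxa) + 2
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_chars};\n")
        fh.write(f'  FORMAT DATATYPE=STANDARD MISSING=? GAP=- SYMBOLS="{symbols}";\n')
        fh.write("  MATRIX\n")
        for i, t in enumerate(matrix.taxa):
            row = "".join(
                "?" if s == MISSING else SYMBOLS[s] for s in matrix.states[i]
            )
            fh.write(f"    {t.replace(' ', '_'):<{width}}{row}\n")
        fh.write("  ;\nEND;\n")


# ---------------------------------------------------------------------------
# character treatment


def filter_max_states(matrix: CharacterMatrix, max_k: int = 10) -> CharacterMatrix:
    """Drop characters whose declared state count exceeds ``max_k``."""
    if max_k < 2:
        raise ValueError("max_k must be >= 2")
    keep = matrix.declared_k <= max_k
    dropped = [cid for cid, k in zip(matrix.char_id, keep) if not k]
    if dropped:
        log.info("filter_max_states: removed %d characters: %s",
                 len(dropped), ", ".join(dropped[:20]))
    if not keep.any():
        log.warning("filter_max_states: no characters retained")
    return matrix.select(keep)


def assign_state_counts(
    matrix: CharacterMatrix,
    scheme: str = "observed",
    annotations: dict[str, int] | None = None,
) -> CharacterMatrix:
    """Fix each character's modelled state-space size ``k``.

    ``observed``
        ``k`` = number of distinct states seen among the sampled taxa;
        states are recoded densely to ``0..k-1`` and characters showing
        fewer than two states are dropped (they carry no Mk likelihood
        signal).
    ``annotated``
        ``k`` is taken from external per-character annotations (e.g. the
        matrix's character notes); original state labels are kept and
        sample-invariant characters are retained, acting as invariable
        sites — the reduced-ascertainment-bias treatment.
    """
    if scheme == "observed":
        states = matrix.states.copy()
        keep = np.zeros(matrix.n_chars, dtype=bool)
        new_k = matrix.declared_k.copy()
        for c in range(matrix.n_chars):
            col = states[:, c]
            obs = np.unique(col[col != MISSING])
            if len(obs) < 2:
                continue
            keep[c] = True
            lut = {int(s): i for i, s in enumerate(sorted(obs))}
            states[:, c] = [lut.get(int(s), MISSING) for s in col]
            new_k[c] = len(obs)
        dropped = [cid for cid, k in zip(matrix.char_id, keep) if not k]
        if dropped:
            log.info("assign_state_counts(observed): dropped %d invariant "
                     "characters: %s", len(dropped), ", ".join(dropped[:20]))
        out = replace(matrix, states=states, declared_k=new_k)
        return out.select(keep)
    if scheme == "annotated":
        if annotations is None:
            raise ValueError("annotated scheme requires annotations")
        missing_ann = [cid for cid in matrix.char_id if cid not in annotations]
        if missing_ann:
            raise ValueError(f"no annotation for characters: {missing_ann[:10]}")
        new_k = np.array([annotations[cid] for cid in matrix.char_id], dtype=np.int64)
        obs_max = np.where(
            (matrix.states != MISSING).any(axis=0),
            matrix.states.max(axis=0, initial=MISSING),
            -1,
        )
        bad = new_k <= obs_max
        if bad.any():
            c = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"character {matrix.char_id[c]}: annotated k={new_k[c]} "
                f"smaller than observed state space"
            )
        if new_k.size and new_k.min() < 2:
            raise ValueError("annotated k must be >= 2")
        return replace(matrix, declared_k=new_k)
    raise ValueError(f"unknown state-count scheme {scheme!r}")


# ---------------------------------------------------------------------------
# trees, annotation tables, traces, config


def read_newick_tree(path) -> TimeTree:
    """Read a rooted binary ultrametric tree with branch lengths in Myr."""
    try:
        dtree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise TreeError(f"cannot parse Newick file {path}: {exc}") from exc
    return TimeTree.from_dendropy(dtree)


def write_newick_tree(tree: TimeTree, path, ages: np.ndarray | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick(ages) + "\n")


def write_annotations(matrix: CharacterMatrix, path) -> None:
    """Per-character table: char_id, declared k, partition label."""
    pd.DataFrame(
        {
            "char_id": matrix.char_id,
            "k": matrix.declared_k,
            "partition": matrix.partition_label,
        }
    ).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"char_id": str, "partition": str})
    need = {"char_id", "k", "partition"}
    if not need <= set(df.columns):
        raise MatrixParseError(f"annotation table {path} lacks columns {need}")
    return df


def apply_annotations(matrix: CharacterMatrix, ann: pd.DataFrame) -> CharacterMatrix:
    """Attach partition labels (and leave k assignment to assign_state_counts)."""
    lut = dict(zip(ann["char_id"], ann["partition"]))
    labels = [lut.get(cid, "all") for cid in matrix.char_id]
    return replace(matrix, partition_label=labels)


def write_trace_tsv(trace: pd.DataFrame, path) -> None:
    """Tab-separated trace, full float precision (round-trip exact)."""
    trace.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_trace_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def read_config(path) -> dict:
    """Parse a flat ``key = value`` run-configuration file.

    Values are coerced to int/float/bool where possible; '#' starts a
    comment.  The recognised keys are the RunConfig fields plus the model
    toggles documented in the README.
    """
    out: dict[str, object] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, val = (s.strip() for s in line.split("=", 1))
            for cast in (int, float):
                try:
                    out[key] = cast(val)
                    break
                except ValueError:
                    continue
            else:
                if val.lower() in ("true", "false"):
                    out[key] = val.lower() == "true"
                else:
                    out[key] = val
    return out
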