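"""Data model and file I/O for perturbation signatures, gene sets and ranks.

The central containers mirror what connectivity-mapping pipelines pass
around: a shared :class:`GeneUniverse`, one z-score vector per compound
(:class:`RankedSignature`), a :class:`CompoundLibrary` holding many of them,
and a :class:`DiseaseSignature` of up-/down-regulated gene sets.

Matrices travel as GCT 1.2 text (or plain headered TSV); gene sets travel
as GMT.  Gene identifiers are opaque strings — no species or ID-namespace
assumption is made.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneUniverse",
    "RankedSignature",
    "DiseaseSignature",
    "CompoundLibrary",
    "rank_transform",
    "read_gct",
    "write_gct",
    "read_gmt",
    "write_gmt",
]


class SigIOError(ValueError):
    """Raised for malformed signature / gene-set inputs."""


@dataclass(frozen=True)
class GeneUniverse:
    """Ordered, duplicate-free list of gene identifiers.

    The order is canonical: every z-vector and rank vector that references
    this universe is aligned to it positionally.
    """

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise SigIOError("gene universe must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            seen: set[str] = set()
            for g in self.genes:
                if g in seen:
                    raise SigIOError(f"duplicate gene identifier in universe: {g!r}")
                seen.add(g)
        object.__setattr__(self, "genes", tuple(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.index

    @property
    def index(self) -> Mapping[str, int]:
        # cached lazily; frozen dataclass so stash on __dict__
        idx = self.__dict__.get("_index")
        if idx is None:
            idx = {g: i for i, g in enumerate(self.genes)}
            self.__dict__["_index"] = idx
        return idx

    @property
    def lex_rank(self) -> np.ndarray:
        """Position of each gene in the lexicographic ordering of ids.

        Used as the deterministic tie-break key when ranking z-scores.
        """
        lr = self.__dict__.get("_lex_rank")
        if lr is None:
            order = np.argsort(np.asarray(self.genes), kind="stable")
            lr = np.empty(len(self.genes), dtype=np.int64)
            lr[order] = np.arange(len(self.genes))
            self.__dict__["_lex_rank"] = lr
        return lr

    def positions(self, genes: Iterable[str]) -> np.ndarray:
        """Integer positions of ``genes`` in the universe (error if absent)."""
        idx = self.index
        try:
            return np.array([idx[g] for g in genes], dtype=np.int64)
        except KeyError as exc:
            raise SigIOError(f"gene not in universe: {exc.args[0]!r}") from None


def rank_transform(z: np.ndarray, universe: GeneUniverse) -> np.ndarray:
    """Descending ranks 1..n of ``z`` (1 = most up-regulated).

    Ties are broken by ascending gene-identifier lexicographic order, which
    makes the ranking a deterministic permutation on every platform.

    Raises on non-finite scores.
    """
    z = np.asarray(z, dtype=float)
    if z.shape != (len(universe),):
        raise SigIOError(
            f"z has length {z.shape}, universe has {len(universe)} genes"
        )
    if not np.all(np.isfinite(z)):
        bad = int(np.flatnonzero(~np.isfinite(z))[0])
        raise SigIOError(f"non-finite z-score for gene {universe.genes[bad]!r}")
    # lexsort: last key is primary -> sort by -z, ties by lexicographic id
    order = np.lexsort((universe.lex_rank, -z))
    ranks = np.empty(len(z), dtype=np.int64)
    ranks[order] = np.arange(1, len(z) + 1)
    return ranks


@dataclass(frozen=True)
class RankedSignature:
    """One compound's gene-level perturbation profile.

    ``z`` holds a real score per gene aligned to ``universe``; ``rank`` is
    the induced descending ranking (permutation of 1..n, 1 = most
    up-regulated), computed via :func:`rank_transform`.
    """

    compound_id: str
    universe: GeneUniverse
    z: np.ndarray
    rank: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "z", z)
        if self.rank is None:
            object.__setattr__(self, "rank", rank_transform(z, self.universe))
        else:
            object.__setattr__(self, "rank", np.asarray(self.rank, dtype=np.int64))


@dataclass(frozen=True)
class DiseaseSignature:
    """Named up- and down-regulated gene sets of a disease expression state."""

    name: str
    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        up = frozenset(self.up)
        down = frozenset(self.down)
        overlap = up & down
        if overlap:
            raise SigIOError(
                f"disease signature {self.name!r}: genes in both up and down sets: "
                f"{sorted(overlap)[:5]}"
            )
        object.__setattr__(self, "up", up)
        object.__setattr__(self, "down", down)

    def harmonize(self, universe: GeneUniverse) -> "DiseaseSignature":
        """Drop genes absent from ``universe``, logging the dropped count.

        Raises if either set ends up empty (no scoreable genes).
        """
        keep_up = frozenset(g for g in self.up if g in universe)
        keep_down = frozenset(g for g in self.down if g in universe)
        n_dropped = (len(self.up) - len(keep_up)) + (len(self.down) - len(keep_down))
        if n_dropped:
            logger.warning(
                "disease signature %s: dropped %d gene(s) absent from the "
                "compound universe", self.name, n_dropped,
            )
        if not keep_up or not keep_down:
            raise SigIOError(
                f"disease signature {self.name!r}: no scoreable genes after "
                "harmonization to the compound universe"
            )
        return DiseaseSignature(self.name, keep_up, keep_down)


@dataclass
class CompoundLibrary:
    """A z-score matrix over a shared gene universe, one column per compound."""

    universe: GeneUniverse
    signatures: dict[str, RankedSignature]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sig in self.signatures.values():
            if sig.universe is not self.universe and sig.universe != self.universe:
                raise SigIOError(
                    f"signature {sig.compound_id!r} uses a different gene universe"
                )

    def __len__(self) -> int:
        return len(self.signatures)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.signatures)

    def matrix(self) -> np.ndarray:
        """Gene x compound z matrix in library column order."""
        return np.column_stack([s.z for s in self.signatures.values()])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   metadata: dict[str, str] | None = None) -> "CompoundLibrary":
        """Build a library from a gene x compound DataFrame (index = genes)."""
        universe = GeneUniverse(tuple(str(g) for g in frame.index))
        sigs = {
            str(c): RankedSignature(str(c), universe, frame[c].to_numpy(dtype=float))
            for c in frame.columns
        }
        return cls(universe, sigs, metadata or {})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix(), index=list(self.universe.genes),
            columns=self.compound_ids,
        )


# ---------------------------------------------------------------------------
# GCT / TSV matrix I/O
# ---------------------------------------------------------------------------

def read_gct(path: str | Path) -> CompoundLibrary:
    """Read a compound library from GCT 1.2 or plain headered gene x compound TSV.

    Row order defines the gene universe; ranks are computed on load.
    Errors name the offending gene / cell for duplicate rows, non-numeric
    cells, or a GCT dimensions line inconsistent with the body.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")

    expected_dims: tuple[int, int] | None = None
    if first.startswith("#1.2"):
        with path.open("r", encoding="utf-8") as fh:
            fh.readline()
            dims_line = fh.readline().split("\t")
            try:
                expected_dims = (int(dims_line[0]), int(dims_line[1]))
            except (ValueError, IndexError):
                raise SigIOError(f"{path}: malformed GCT dimensions line") from None
            body = pd.read_csv(fh, sep="\t", dtype={0: str}, index_col=0,
                               float_precision="round_trip")
        if "Description" in body.columns:
            body = body.drop(columns=["Description"])
        elif len(body.columns) > 0:
            # GCT 1.2 mandates a second annotation column whatever its label
            body = body.drop(columns=[body.columns[0]])
    else:
        body = pd.read_csv(path, sep="\t", dtype={0: str}, index_col=0,
                           float_precision="round_trip")

    if body.index.has_duplicates:
        dup = body.index[body.index.duplicated()][0]
        raise SigIOError(f"{path}: duplicate gene row {dup!r}")
    if expected_dims is not None and expected_dims != body.shape:
        raise SigIOError(
            f"{path}: dimensions line declares {expected_dims[0]} genes x "
            f"{expected_dims[1]} compounds but body is "
            f"{body.shape[0]} x {body.shape[1]}"
        )
    for col in body.columns:
        numeric = pd.to_numeric(body[col], errors="coerce")
        bad = numeric.isna() & body[col].notna()
        if bad.any():
            gene = body.index[bad.argmax()]
            raise SigIOError(
                f"{path}: non-numeric cell at gene {gene!r}, compound {col!r}"
            )
        body[col] = numeric
    if body.isna().any().any():
        gene = body.index[body.isna().any(axis=1).argmax()]
        raise SigIOError(f"{path}: missing value at gene {gene!r}")
    return CompoundLibrary.from_frame(body.astype(float))


def write_gct(lib: CompoundLibrary, path: str | Path) -> None:
    """Write the library as GCT 1.2 TSV.

    Values are written at full (shortest round-trip) precision so that
    ``read_gct(write_gct(lib))`` reproduces the z-matrix cell for cell.
    """
    path = Path(path)
    frame = lib.to_frame()
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("#1.2\n")
        fh.write(f"{frame.shape[0]}\t{frame.shape[1]}\n")
        fh.write("NAME\tDescription\t" + "\t".join(frame.columns) + "\n")
        for gene, row in zip(frame.index, frame.to_numpy()):
            cells = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{gene}\tna\t{cells}\n")


# ---------------------------------------------------------------------------
# GMT gene-set I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, universe: GeneUniverse,
             name: str | None = None) -> DiseaseSignature:
    """Read a disease signature from GMT lines ``<name>_UP`` / ``<name>_DOWN``.

    Genes absent from ``universe`` are dropped with a logged count;
    missing UP or DOWN line, or an empty post-harmonization set, is an error.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)

    suffixes = {"_UP": {}, "_DOWN": {}}
    for set_name, genes in sets.items():
        for suf in suffixes:
            if set_name.endswith(suf):
                suffixes[suf][set_name[: -len(suf)]] = genes
    names = set(suffixes["_UP"]) & set(suffixes["_DOWN"])
    if name is not None:
        if name not in names:
            missing = "_DOWN" if name in suffixes["_UP"] else "_UP"
            raise SigIOError(f"{path}: missing {name}{missing} line")
        chosen = name
    else:
        if not names:
            raise SigIOError(
                f"{path}: need both <name>_UP and <name>_DOWN gene-set lines"
            )
        chosen = sorted(names)[0]
    raw = DiseaseSignature(chosen, suffixes["_UP"][chosen], suffixes["_DOWN"][chosen])
    return raw.harmonize(universe)


def write_gmt(disease: DiseaseSignature, path: str | Path) -> None:
    """Write the up/down sets as two GMT lines (sorted gene order)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join([f"{disease.name}_UP", "na", *sorted(disease.up)]) + "\n")
        fh.write("\t".join([f"{disease.name}_DOWN", "na", *sorted(disease.down)]) + "\n")
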