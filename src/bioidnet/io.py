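"""Shared data model and tabular readers/writers.

All dialects are plain UTF-8 tab-separated text with a mandatory header row
(except seed lists, which are one symbol per line, and GMT category files).
Gene symbols are matched exactly and case-sensitively; callers that want
case folding pass ``upper_case=True`` to the readers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("bioidnet.io")

CONDITIONS = ("bait", "control")
SPECIFICITY_CLASSES = ("specific", "nonspecific", "unobserved")


class ParseError(ValueError):
    """An input file violates the expected dialect or an invariant."""


class NumericError(RuntimeError):
    """A numeric routine failed to converge or produced invalid output."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PsmMatrix:
    """Protein x sample spectral-count matrix with the sample design.

    ``counts`` rows are proteins, columns are samples.  ``condition`` and
    ``replicate`` are indexed by sample id; conditions are 'bait' or
    'control'.  Counts are nonnegative; missing observations are NaN until
    :func:`bioidnet.diffexp.impute_missing` sets them to 0.
    """

    counts: pd.DataFrame
    condition: pd.Series
    replicate: pd.Series

    def __post_init__(self) -> None:
        # float64 storage of integer-valued counts (NaN marks missing cells)
        self.counts = self.counts.rename_axis("protein_id").astype(float)
        if self.counts.index.duplicated().any():
            dups = sorted(set(self.counts.index[self.counts.index.duplicated()]))
            raise ParseError(f"duplicate protein ids: {', '.join(dups)}")
        if not self.counts.columns.equals(self.condition.index):
            raise ParseError("sample columns and design samples do not match")
        bad = set(self.condition) - set(CONDITIONS)
        if bad:
            raise ParseError(f"unknown conditions: {sorted(bad)}")
        for cond in CONDITIONS:
            if (self.condition == cond).sum() < 1:
                raise ParseError(f"no sample with condition '{cond}'")
        with np.errstate(invalid="ignore"):
            if (self.counts.to_numpy() < 0).any():
                raise ParseError("negative PSM counts")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples(self, condition: str) -> list[str]:
        return list(self.condition.index[self.condition == condition])


@dataclass
class FunctionalNetwork:
    """Weighted undirected association network over protein symbols.

    Edge weights are combined association scores in (0, 1].  The input
    representation carries no self-edges and no duplicate pairs.
    """

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"protein1": min(u, v), "protein2": max(u, v), "combined_score": d["weight"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])
        return df.sort_values(["protein1", "protein2"]).reset_index(drop=True)

    def adjacency(self, order: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
        order = self.nodes if order is None else list(order)
        a = nx.to_numpy_array(self.graph, nodelist=order, weight="weight")
        return a, order


@dataclass
class SeedSet:
    """Phenotype-associated seed genes with their initial heat (default 1)."""

    heat: dict[str, float]

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.heat.values()):
            raise ParseError("seed heat must be > 0")

    @property
    def genes(self) -> list[str]:
        return sorted(self.heat)


@dataclass
class SpecificityReference:
    """Per-protein interaction-specificity class from a bait/control survey.

    Proteins absent from the survey are 'unobserved' (potential new
    interactors).
    """

    classes: dict[str, str]
    provenance: str = ""

    def __post_init__(self) -> None:
        bad = set(self.classes.values()) - set(SPECIFICITY_CLASSES)
        if bad:
            raise ParseError(f"unknown specificity classes: {sorted(bad)}")

    def classify(self, symbol: str) -> str:
        return self.classes.get(symbol, "unobserved")


@dataclass
class CategorySets:
    """Named gene sets with GMT semantics (name, description, members)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [n for n, m in self.sets.items() if not m]
        if empty:
            raise ParseError(f"empty category sets: {empty}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> dict[str, tuple[str, int]]:
    """Read a two-column design TSV: sample_id, condition[:replicate]."""
    design: dict[str, tuple[str, int]] = {}
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: design needs two columns (sample_id, condition)")
    for _, row in df.iterrows():
        sample, spec = str(row.iloc[0]), str(row.iloc[1])
        if ":" in spec:
            cond, rep = spec.split(":", 1)
            try:
                repn = int(rep)
            except ValueError as exc:
                raise ParseError(f"{path}: bad replicate '{rep}' for {sample}") from exc
        else:
            cond, repn = spec, 1
        design[sample] = (cond, repn)
    return design


def read_psm_table(
    path: str | Path,
    design: Mapping[str, tuple[str, int]],
    upper_case: bool = False,
    impute: bool = True,
) -> PsmMatrix:
    """Read a PSM count TSV (protein_id column + one numeric column per sample).

    Cells must parse as numbers.  Absent cells become 0 (peptide not detected);
    pass ``impute=False`` to keep them as NaN for explicit imputation.
    Samples named in the design must all be present in the file.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if upper_case:
        df.index = df.index.str.upper()
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ParseError(f"{path}: duplicate protein ids: {', '.join(dups)}")
    missing = [s for s in design if s not in df.columns]
    if missing:
        raise ParseError(f"{path}: design samples missing from file: {missing}")
    df = df[list(design)]
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        raw_na = df[col].isna()
        if (vals.isna() & ~raw_na).any():
            bad = df.index[vals.isna() & ~raw_na][0]
            raise ParseError(f"{path}: unparseable count for {bad} / {col}")
        df[col] = vals
    condition = pd.Series({s: design[s][0] for s in df.columns}, name="condition")
    replicate = pd.Series({s: design[s][1] for s in df.columns}, name="replicate")
    # integer counts where observed; NaN marks missing cells
    observed = df.notna()
    if not np.allclose(df.to_numpy()[observed.to_numpy()] % 1, 0):
        raise ParseError(f"{path}: non-integer PSM counts")
    if impute:
        df = df.fillna(0.0)
    return PsmMatrix(counts=df, condition=condition[df.columns], replicate=replicate[df.columns])


def read_edge_list(
    path: str | Path,
    score_cutoff: float = 0.4,
    upper_case: bool = False,
) -> FunctionalNetwork:
    """Read a STRING-dialect edge TSV (protein1, protein2, combined_score).

    Edges with score <= ``score_cutoff`` are dropped (the cutoff is strict:
    only scores above it are kept), self-edges are dropped, and reciprocal
    duplicates are merged keeping the maximum score.  Scores outside (0, 1]
    raise an error naming the row.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ParseError(f"{path}: edge list needs 3 columns")
    g = nx.Graph()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        u, v = str(row[0]), str(row[1])
        if upper_case:
            u, v = u.upper(), v.upper()
        score = float(row[2])
        if not (0.0 < score <= 1.0):
            raise ParseError(f"{path}: line {i}: score {score} outside (0, 1]")
        if u == v:
            continue
        if score <= score_cutoff:
            continue
        if g.has_edge(u, v):
            g[u][v]["weight"] = max(g[u][v]["weight"], score)
        else:
            g.add_edge(u, v, weight=score)
    return FunctionalNetwork(graph=g)


def read_seeds(path: str | Path, heat: float = 1.0, upper_case: bool = False) -> SeedSet:
    """Read a seed-gene list, one symbol per line; each seed gets ``heat``."""
    genes = []
    for line in Path(path).read_text().splitlines():
        sym = line.strip()
        if not sym or sym.startswith("#"):
            continue
        genes.append(sym.upper() if upper_case else sym)
    if len(genes) != len(set(genes)):
        dups = sorted({g for g in genes if genes.count(g) > 1})
        raise ParseError(f"{path}: duplicate seeds: {dups}")
    return SeedSet(heat={g: heat for g in genes})


def read_specificity(path: str | Path, upper_case: bool = False) -> SpecificityReference:
    """Read a two-column specificity TSV (protein, class)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    classes = {}
    for _, row in df.iterrows():
        sym = str(row.iloc[0])
        if upper_case:
            sym = sym.upper()
        classes[sym] = str(row.iloc[1])
    return SpecificityReference(classes=classes, provenance=str(path))


def read_gmt(path: str | Path, upper_case: bool = False) -> CategorySets:
    """Read category sets in GMT format (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}: GMT line needs name, description, >=1 member")
        name, desc, members = parts[0], parts[1], parts[2:]
        if name in sets:
            raise ParseError(f"{path}: duplicate category name '{name}'")
        members = [m.upper() for m in members if m] if upper_case else [m for m in members if m]
        sets[name] = members
        descriptions[name] = desc
    return CategorySets(sets=sets, descriptions=descriptions)


# ---------------------------------------------------------------------------
# writers (stable column order, deterministic formatting)
# ---------------------------------------------------------------------------

def write_psm_table(psm: PsmMatrix, path: str | Path) -> None:
    out = psm.counts.copy()
    out.index.name = "protein_id"
    # render observed counts as integers, keep missing cells empty
    out = out.map(lambda x: "" if pd.isna(x) else str(int(x)))
    out.to_csv(path, sep="\t")


def write_design(psm: PsmMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tcondition\n")
        for s in psm.sample_ids:
            fh.write(f"{s}\t{psm.condition[s]}:{psm.replicate[s]}\n")


def write_edge_list(net: FunctionalNetwork, path: str | Path) -> None:
    df = net.edge_table()
    df["combined_score"] = df["combined_score"].map(lambda w: f"{w:.6g}")
    df.to_csv(path, sep="\t", index=False)


def write_seeds(seeds: SeedSet, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in seeds.genes))


def write_specificity(ref: SpecificityReference, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tclass\n")
        for sym in sorted(ref.classes):
            fh.write(f"{sym}\t{ref.classes[sym]}\n")


def write_gmt(cats: CategorySets, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in cats.sets:
            desc = cats.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *cats.sets[name]]) + "\n")


def write_table(df: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> None:
    """Write an output table as TSV with stable column order and formatting."""
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
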