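"""Readers and writers for every table the pipeline touches.

All tables are tab-separated UTF-8 text with a header row; lines starting
with ``#`` are comments. Count-table sample columns follow the grammar
``line|replicate|day`` (e.g. ``HCT116par|r1|d6`` or ``HCT116par|r1|6``),
which parses into the three-level sample index ``(line, replicate, day)``.

Every reader/writer pair is a lossless round trip on valid data, and
readers raise typed errors (:class:`~dienet.errors.FormatError`,
:class:`~dienet.errors.IntegrityError`) naming the offending row or column
rather than silently coercing.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError

SAMPLE_LEVELS = ("line", "replicate", "day")

_READ_KWARGS = dict(sep="\t", comment="#", dtype=str)

EDGE_COLUMNS = ["query", "gene", "dgarp", "p", "confirmed", "conserved"]


def parse_sample_name(name: str) -> tuple[str, str, float]:
    """Parse a ``line|replicate|day`` column name into its sample key.

    The day field may carry a leading ``d`` (``d6`` and ``6`` both parse
    to 6.0).
    """
    parts = name.split("|")
    if len(parts) != 3:
        raise FormatError(
            f"sample column {name!r}: expected 'line|replicate|day' with two '|'"
        )
    line, replicate, day = parts
    m = re.fullmatch(r"d?([0-9]+(?:\.[0-9]+)?)", day)
    if not line or not replicate or m is None:
        raise FormatError(f"sample column {name!r}: unparsable day field {day!r}")
    return line, replicate, float(m.group(1))


def format_sample_name(line: str, replicate: str, day: float) -> str:
    day_str = f"{day:g}"
    return f"{line}|{replicate}|d{day_str}"


def _sample_index(names) -> pd.MultiIndex:
    keys = [parse_sample_name(n) for n in names]
    idx = pd.MultiIndex.from_tuples(keys, names=SAMPLE_LEVELS)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise IntegrityError(f"duplicate sample column {dup}")
    return idx


def read_hairpin_map(path) -> pd.DataFrame:
    """Read a hairpin→gene annotation table.

    Expects header columns ``hairpin`` and ``gene`` (optional
    ``sequence``). Hairpin ids must be unique; each hairpin maps to
    exactly one gene.
    """
    df = pd.read_csv(path, **_READ_KWARGS)
    missing = {"hairpin", "gene"} - set(df.columns)
    if missing:
        raise FormatError(f"hairpin map missing column(s): {sorted(missing)}")
    if df["hairpin"].duplicated().any():
        dup = df.loc[df["hairpin"].duplicated(), "hairpin"].iloc[0]
        raise IntegrityError(f"duplicate hairpin id {dup!r}")
    if df[["hairpin", "gene"]].isna().any().any():
        raise FormatError("hairpin map contains empty hairpin or gene fields")
    cols = ["hairpin", "gene"] + (["sequence"] if "sequence" in df.columns else [])
    return df[cols].reset_index(drop=True)


def write_hairpin_map(hairpin_map: pd.DataFrame, path) -> None:
    hairpin_map.to_csv(path, sep="\t", index=False)


def read_count_table(path) -> pd.DataFrame:
    """Read a hairpin × sample read-count table.

    First column is ``hairpin``; every remaining column name must parse
    as ``line|replicate|day``. Counts must be nonnegative integers.
    Returns a DataFrame indexed by hairpin with a ``(line, replicate,
    day)`` MultiIndex on the columns.
    """
    df = pd.read_csv(path, **_READ_KWARGS)
    if df.shape[1] < 2 or df.columns[0] != "hairpin":
        raise FormatError("count table must start with a 'hairpin' column")
    df = df.set_index("hairpin")
    if df.index.duplicated().any():
        raise IntegrityError(
            f"duplicate hairpin row {df.index[df.index.duplicated()][0]!r}"
        )
    counts = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        try:
            counts[:, j] = df[col].astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"non-integer count in column {col!r}: {exc}") from exc
        if (counts[:, j] < 0).any():
            row = df.index[np.argmax(counts[:, j] < 0)]
            raise FormatError(f"negative count at row {row!r}, column {col!r}")
    out = pd.DataFrame(counts, index=df.index, columns=_sample_index(df.columns))
    return out


def write_count_table(counts: pd.DataFrame, path) -> None:
    flat = counts.copy()
    flat.columns = [format_sample_name(*key) for key in counts.columns]
    flat.index.name = "hairpin"
    flat.to_csv(path, sep="\t")


def read_expression_table(path) -> pd.DataFrame:
    """Read a gene × line log2-expression matrix (first column ``gene``)."""
    df = pd.read_csv(path, **_READ_KWARGS)
    if df.shape[0] == 0 or df.shape[1] < 2 or df.columns[0] != "gene":
        raise FormatError("expression table must have a 'gene' column and ≥1 line")
    df = df.set_index("gene")
    if df.index.duplicated().any():
        raise IntegrityError(
            f"duplicate gene row {df.index[df.index.duplicated()][0]!r}"
        )
    try:
        values = df.astype(float)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric expression value: {exc}") from exc
    if not np.isfinite(values.to_numpy()).all():
        raise FormatError("expression table contains non-finite values")
    return values


def write_expression_table(expression: pd.DataFrame, path) -> None:
    out = expression.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def write_edge_list(edges: pd.DataFrame, path) -> None:
    """Write a DiE edge list with deterministic ordering.

    Rows are sorted by (query, gene); the ``confirmed``/``conserved``
    flags serialize as 0/1. Duplicate (query, gene) pairs are rejected.
    """
    edges = edges.reindex(columns=EDGE_COLUMNS)
    if edges[["query", "gene"]].duplicated().any():
        dup = edges.loc[edges[["query", "gene"]].duplicated(), ["query", "gene"]]
        raise IntegrityError(f"duplicate edge {tuple(dup.iloc[0])}")
    out = edges.sort_values(["query", "gene"], kind="stable").copy()
    out["confirmed"] = out["confirmed"].astype(bool).astype(int)
    out["conserved"] = out["conserved"].astype(bool).astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, **_READ_KWARGS)
    missing = set(EDGE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"edge list missing column(s): {sorted(missing)}")
    if df.shape[0] == 0:
        return pd.DataFrame(columns=EDGE_COLUMNS).astype(
            {"dgarp": float, "p": float, "confirmed": bool, "conserved": bool}
        )
    try:
        df["dgarp"] = df["dgarp"].astype(float)
        df["p"] = df["p"].astype(float)
        df["confirmed"] = df["confirmed"].astype(int).astype(bool)
        df["conserved"] = df["conserved"].astype(int).astype(bool)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"edge list has non-numeric fields: {exc}") from exc
    if ((df["p"] <= 0) | (df["p"] > 1)).any():
        bad = df.loc[(df["p"] <= 0) | (df["p"] > 1)].index[0]
        raise FormatError(f"edge list p-value out of (0,1] at row {bad}")
    if df[["query", "gene"]].duplicated().any():
        dup = df.loc[df[["query", "gene"]].duplicated(), ["query", "gene"]]
        raise IntegrityError(f"duplicate edge {tuple(dup.iloc[0])}")
    return df[EDGE_COLUMNS]


def write_sif(edges: pd.DataFrame, path, interaction: str = "ssl") -> None:
    """Export edges as SIF (``node<TAB>interaction<TAB>node``) for viewers."""
    out = edges.sort_values(["query", "gene"], kind="stable")
    with open(path, "w", encoding="utf-8") as fh:
        for _, row in out.iterrows():
            fh.write(f"{row['query']}\t{interaction}\t{row['gene']}\n")


def write_gmt(gene_sets: dict, path) -> None:
    """Write gene sets as GMT (``name<TAB>description<TAB>gene...``)."""
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\tdienet\t{genes}\n")


def read_gmt(path) -> dict:
    """Read gene sets from a GMT file; returns name → set of genes."""
    sets: dict[str, set] = {}
    with open(path, encoding="utf-8") as fh:
        for i, raw in enumerate(fh):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"GMT line {i + 1}: need name and description")
            if parts[0] in sets:
                raise IntegrityError(f"duplicate gene set {parts[0]!r}")
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def read_score_table(path) -> pd.DataFrame:
    """Read a per-gene score table (gene, garp, zgarp, p, n_hairpins)."""
    df = pd.read_csv(path, **_READ_KWARGS)
    missing = {"gene", "garp", "zgarp", "p", "n_hairpins"} - set(df.columns)
    if missing:
        raise FormatError(f"score table missing column(s): {sorted(missing)}")
    df = df.set_index("gene")
    try:
        return df.astype(
            {"garp": float, "zgarp": float, "p": float, "n_hairpins": int}
        )
    except (ValueError, TypeError) as exc:
        raise FormatError(f"score table has non-numeric fields: {exc}") from exc


def write_score_table(scores: pd.DataFrame, path) -> None:
    out = scores.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
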