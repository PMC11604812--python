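"""Tabular I/O: expression / sample / probe-map TSVs and GMT gene-set files.

Conventions (shared by the synthetic generator and the pipeline):

* expression TSV — first column ``feature_id`` (probe or gene symbol),
  header row of sample ids, log-scale intensities;
* sample TSV — columns ``sample_id, diagnosis (SZ|CTRL), age, sex (M|F),
  dataset_id`` plus optional ``true_subtype`` / ``cluster``;
* probe-map TSV — two columns ``probe_id, gene_symbol``;
* GMT — one set per line: name, description, then member genes, tab-separated.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col=0)
    if m.index.has_duplicates and m.index.name != "probe_id":
        dups = m.index[m.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate feature ids in {path}: {dups} ...")
    if m.columns.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    return m


def write_expression_tsv(m: pd.DataFrame, path: str | Path) -> None:
    m.to_csv(path, sep="\t", index_label=m.index.name or "feature_id")


def read_sample_tsv(path: str | Path) -> pd.DataFrame:
    s = pd.read_csv(path, sep="\t", index_col="sample_id")
    missing = {"diagnosis"} - set(s.columns)
    if missing:
        raise ValueError(f"sample table {path} lacks required columns: {sorted(missing)}")
    return s


def write_sample_tsv(s: pd.DataFrame, path: str | Path) -> None:
    s.to_csv(path, sep="\t", index_label="sample_id")


def read_probe_map_tsv(path: str | Path) -> pd.Series:
    pm = pd.read_csv(path, sep="\t", index_col=0).iloc[:, 0]
    pm.name = "gene_symbol"
    return pm


def write_probe_map_tsv(pm: pd.Series, path: str | Path) -> None:
    pm.to_frame("gene_symbol").to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> dict[str, dict]:
    """Read a GMT file into ``{set_name: {"description": ..., "genes": [...]}}``."""
    sets: dict[str, dict] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
        name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        if not genes:
            raise ValueError(f"{path}:{lineno}: set {name!r} is empty")
        sets[name] = {"description": desc, "genes": genes}
    return sets


def write_gmt(sets: dict[str, dict], path: str | Path) -> None:
    lines = []
    for name, body in sets.items():
        genes = body["genes"] if isinstance(body, dict) else list(body)
        desc = body.get("description", "") if isinstance(body, dict) else ""
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")
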