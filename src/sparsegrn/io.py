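"""File formats: steady-state expression tables, gold standards, predictions.

The steady-state format is the DREAM-challenge convention: tab-separated,
a header row of gene names (``G1 ... Gn``), the wild-type file carrying a
single data row of unperturbed levels and the knockout file carrying n
rows, row l being the steady state reached after deleting gene l.  Gold
standards and predictions are tab-separated edge lists
``G<regulator>\tG<target>\t<value>``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .grn import NetworkEstimate, PerturbationDataset

__all__ = [
    "read_dream_steady_state",
    "read_gold_standard",
    "write_edge_predictions",
    "read_edge_predictions",
    "write_dream_steady_state",
]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if df.columns.str.match(r"^[-+0-9.eE]+$").any():
        raise ValueError(f"{path}: header row of gene names is missing")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise ValueError(
                f"{path}: non-numeric value {df[col][row]!r} at data row "
                f"{row + 1}, column {col!r}"
            )
        df[col] = vals
    return df


def read_dream_steady_state(
    wildtype_path: str | Path, knockout_path: str | Path
) -> PerturbationDataset:
    """Read wild-type and knockout steady-state tables into a dataset.

    Knockout row ``l`` is labelled as the deletion of gene ``l``.
    """
    wt = _read_table(wildtype_path)
    ko = _read_table(knockout_path)
    if list(wt.columns) != list(ko.columns):
        raise ValueError(
            f"gene columns differ between {wildtype_path} and {knockout_path}"
        )
    if len(wt) != 1:
        raise ValueError(
            f"{wildtype_path}: expected exactly one wild-type row, got {len(wt)}"
        )
    genes = list(wt.columns)
    if len(ko) != len(genes):
        raise ValueError(
            f"{knockout_path}: expected {len(genes)} knockout rows "
            f"(one per gene), got {len(ko)}"
        )
    return PerturbationDataset(
        wildtype=wt.to_numpy()[0],
        perturbed=ko.to_numpy(),
        gene_names=genes,
        perturbation_labels=genes.copy(),
    )


def write_dream_steady_state(
    dataset: PerturbationDataset,
    wildtype_path: str | Path,
    knockout_path: str | Path,
) -> None:
    """Write a dataset back to the two-file steady-state convention."""
    wt = pd.DataFrame([dataset.wildtype], columns=dataset.gene_names)
    ko = pd.DataFrame(dataset.perturbed, columns=dataset.gene_names)
    wt.to_csv(wildtype_path, sep="\t", index=False)
    ko.to_csv(knockout_path, sep="\t", index=False)


def read_gold_standard(path: str | Path, n_genes: int) -> np.ndarray:
    """Read a gold-standard edge list into a binary n x n adjacency.

    Lines are ``G<i>\tG<j>\t{0,1}`` with edge direction regulator to
    target; entry ``(target, regulator)`` of the returned matrix is 1 for
    a true edge, matching the row-is-target adjacency convention.
    """
    gold = np.zeros((n_genes, n_genes))
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
        try:
            reg = int(parts[0].lstrip("G")) - 1
            tgt = int(parts[1].lstrip("G")) - 1
            val = int(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: cannot parse {line!r}") from exc
        if not (0 <= reg < n_genes and 0 <= tgt < n_genes):
            raise ValueError(f"{path}:{lineno}: gene index out of range")
        gold[tgt, reg] = val
    return gold


def write_edge_predictions(
    net: NetworkEstimate, path: str | Path, max_edges: int | None = None
) -> None:
    """Write a descending-score prediction list of off-diagonal edges.

    Lines are ``G<regulator>\tG<target>\t<score>``; zero-score edges are
    omitted, and ties break deterministically by (regulator, target) index.
    """
    scores = net.ranking_scores
    n = scores.shape[0]
    rows = []
    for tgt in range(n):
        for reg in range(n):
            if reg == tgt:
                continue
            s = scores[tgt, reg]
            if s > 0:
                rows.append((reg, tgt, s))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    if max_edges is not None:
        rows = rows[:max_edges]
    with open(path, "w") as fh:
        for reg, tgt, s in rows:
            fh.write(f"G{reg + 1}\tG{tgt + 1}\t{s:.10g}\n")


def read_edge_predictions(path: str | Path, n_genes: int) -> np.ndarray:
    """Read a prediction list back into an n x n ranking-score matrix."""
    scores = np.zeros((n_genes, n_genes))
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
        reg = int(parts[0].lstrip("G")) - 1
        tgt = int(parts[1].lstrip("G")) - 1
        scores[tgt, reg] = float(parts[2])
    return scores
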