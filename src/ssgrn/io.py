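"""Readers/writers, configuration documents, and evaluation reports.

Time series travel as TSV/CSV with a leading "time" column and one column
per gene (dialect sniffed from the header line); models as JSON documents
with named alpha/beta/g/h blocks.  Numeric output uses 17 significant
digits so every round trip is exact.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gapso import GAPSOConfig
from .island import IslandConfig
from .ssystem import ExpressionDataset, SSystemError, SSystemModel

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_model",
    "write_model",
    "load_config",
    "save_config",
    "config_hash",
    "ScatterMetrics",
    "scatter_metrics",
    "RunReport",
    "write_report",
    "write_traces",
]

_FLOAT_FMT = "%.17g"


def _sniff_sep(path: Path) -> str:
    header = path.read_text().splitlines()[0] if path.read_text() else ""
    return "\t" if "\t" in header else ","


def read_timeseries(path: str | Path) -> ExpressionDataset:
    """Read a TSV/CSV time-series matrix (time column first, genes after).

    The delimiter is auto-detected from the header line.  Non-numeric
    cells, non-increasing times and non-positive concentrations are
    reported with their row/column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.shape[1] < 2:
        raise SSystemError("expected a time column plus at least one gene column")
    if df.columns[0].strip().lower() != "time":
        raise SSystemError(
            f"first column must be 'time', found {df.columns[0]!r}"
        )
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.argmax((bad | df[col].isna()).to_numpy()))
            raise SSystemError(
                f"non-numeric value at row {row + 1}, column {col!r}"
            )
    times = df.iloc[:, 0].to_numpy(dtype=float)
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        k = int(np.argmax(np.diff(times) <= 0))
        raise SSystemError(f"time column not strictly increasing at row {k + 2}")
    if np.any(values <= 0):
        r, c = np.argwhere(values <= 0)[0]
        raise SSystemError(
            f"non-positive concentration at row {r + 1}, column {df.columns[c + 1]!r}"
        )
    return ExpressionDataset(
        times=times, values=values, gene_names=list(df.columns[1:])
    )


def write_timeseries(
    dataset: ExpressionDataset, path: str | Path, sep: str = "\t"
) -> None:
    """Write a dataset with 17-significant-digit values (round-trip exact)."""
    path = Path(path)
    cols = ["time"] + dataset.labels()
    with open(path, "w") as fh:
        fh.write(sep.join(cols) + "\n")
        for k in range(dataset.n_times):
            row = [_FLOAT_FMT % dataset.times[k]] + [
                _FLOAT_FMT % v for v in dataset.values[k]
            ]
            fh.write(sep.join(row) + "\n")


def write_model(model: SSystemModel, path: str | Path) -> None:
    """JSON document with named alpha/beta/g/h blocks; round-trip exact."""
    doc = {
        "n_genes": model.n_genes,
        "gene_names": model.gene_names,
        "alpha": [float(v) for v in model.alpha],
        "beta": [float(v) for v in model.beta],
        "g": [[float(v) for v in row] for row in model.g],
        "h": [[float(v) for v in row] for row in model.h],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_model(path: str | Path) -> SSystemModel:
    doc = json.loads(Path(path).read_text())
    try:
        return SSystemModel(
            alpha=np.array(doc["alpha"], dtype=float),
            beta=np.array(doc["beta"], dtype=float),
            g=np.array(doc["g"], dtype=float),
            h=np.array(doc["h"], dtype=float),
            gene_names=doc.get("gene_names"),
        )
    except KeyError as exc:
        raise SSystemError(f"model document is missing block {exc}") from exc


# ---------------------------------------------------------------------------
# configuration documents


def config_document(
    gapso_cfg: GAPSOConfig, island_cfg: IslandConfig | None = None
) -> str:
    """Flat YAML document exposing every optimizer/island setting."""
    doc: dict = {"gapso": _plain(asdict(gapso_cfg))}
    if island_cfg is not None:
        doc["island"] = _plain(asdict(island_cfg))
    return yaml.safe_dump(doc, sort_keys=True)


def save_config(
    path: str | Path,
    gapso_cfg: GAPSOConfig,
    island_cfg: IslandConfig | None = None,
) -> None:
    Path(path).write_text(config_document(gapso_cfg, island_cfg))


def _plain(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            out[k] = [float(x) for x in v]
        else:
            out[k] = v
    return out


def load_config(path: str | Path) -> tuple[GAPSOConfig, IslandConfig | None]:
    doc = yaml.safe_load(Path(path).read_text())
    gapso_cfg = GAPSOConfig(**doc["gapso"])
    island_cfg = IslandConfig(**doc["island"]) if "island" in doc else None
    return gapso_cfg, island_cfg


def config_hash(gapso_cfg: GAPSOConfig, island_cfg: IslandConfig | None = None) -> str:
    """Short stable digest of a configuration, stamped into every artifact."""
    doc = {"gapso": _plain(asdict(gapso_cfg))}
    if island_cfg is not None:
        doc["island"] = _plain(asdict(island_cfg))
    blob = json.dumps(doc, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class ScatterMetrics:
    """Agreement between inferred and actual concentration matrices."""

    r2_per_gene: np.ndarray
    pooled_r2: float
    dot_count: int


def _pearson_r2(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn(
            "degenerate (constant) profile: R-squared undefined, reporting 0",
            stacklevel=3,
        )
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def scatter_metrics(
    inferred: ExpressionDataset, actual: ExpressionDataset
) -> ScatterMetrics:
    """Squared Pearson correlation between inferred and actual profiles.

    Pools all T*N (actual, inferred) pairs for the overall R-squared — one
    dot per gene per time point, as in a concentration scatter plot — and
    also reports R-squared per gene.
    """
    if inferred.values.shape != actual.values.shape:
        raise SSystemError(
            f"shape mismatch: inferred {inferred.values.shape} vs actual {actual.values.shape}"
        )
    per_gene = np.array(
        [
            _pearson_r2(actual.values[:, j], inferred.values[:, j])
            for j in range(actual.n_genes)
        ]
    )
    pooled = _pearson_r2(actual.values.ravel(), inferred.values.ravel())
    return ScatterMetrics(
        r2_per_gene=per_gene,
        pooled_r2=pooled,
        dot_count=actual.n_times * actual.n_genes,
    )


@dataclass
class RunReport:
    """Per-gene inference diagnostics plus reproducibility metadata."""

    per_gene_fitness: np.ndarray
    r2_per_gene: np.ndarray
    pooled_r2: float
    seed: int
    config_digest: str
    duration_s: float = float("nan")

    @property
    def average_fitness_per_gene(self) -> float:
        return float(np.mean(self.per_gene_fitness))


def write_report(report: RunReport, path: str | Path, gene_names: list[str]) -> None:
    """TSV report (one row per gene) with a commented metadata header."""
    with open(Path(path), "w") as fh:
        fh.write(f"# seed={report.seed}\tconfig={report.config_digest}\n")
        fh.write(
            f"# average_fitness_per_gene={_FLOAT_FMT % report.average_fitness_per_gene}"
            f"\tpooled_r2={_FLOAT_FMT % report.pooled_r2}"
            f"\tduration_s={report.duration_s:.3f}\n"
        )
        fh.write("gene\tfitness\tr_squared\n")
        for name, fit, r2 in zip(
            gene_names, report.per_gene_fitness, report.r2_per_gene
        ):
            fh.write(f"{name}\t{_FLOAT_FMT % fit}\t{_FLOAT_FMT % r2}\n")


def write_traces(traces: np.ndarray, path: str | Path, migration_interval: int) -> None:
    """Per-island best-so-far fitness traces as TSV (epoch, iteration, island, gbest)."""
    with open(Path(path), "w") as fh:
        fh.write("epoch\titeration\tisland\tgbest_fitness\n")
        n_islands, n_iter = traces.shape
        for t in range(1, n_iter + 1):
            epoch = t // migration_interval
            for isl in range(n_islands):
                fh.write(f"{epoch}\t{t}\t{isl}\t{_FLOAT_FMT % traces[isl, t - 1]}\n")
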