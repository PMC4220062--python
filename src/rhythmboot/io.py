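"""File formats, run manifests, and format validation.

Expression matrices are tab-delimited text: first column ``gene_id``, then
one column per (timepoint, replicate) sample named ``T<time>_R<rep>``
(e.g. ``T0_R1``, ``T4_R2``); the ``ZT<time>.<rep>`` dialect used by some
published circadian datasets is also accepted.  Replicate structure is
inferred from the headers, timepoints are sorted ascending, and duplicate
gene ids or an incomplete timepoint x replicate grid are format errors.

Every CLI run writes a JSON manifest recording the tool version, master
seed, per-stage sub-seeds, the full configuration, and digests of inputs
and outputs, so a run can be replayed exactly.
"""

from __future__ import annotations

import hashlib
import json
import re
from datetime import datetime, timezone

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .exceptions import FormatError
from .resample import ConsensusTable
from .simdata import ExpressionDataset, TruthLabels

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "write_truth",
    "write_results",
    "write_consensus",
    "RunManifest",
    "write_manifest",
    "read_manifest",
    "file_digest",
]

_HEADER_RES = (
    re.compile(r"^T(?P<time>\d+(?:\.\d+)?)_R(?P<rep>\d+)$"),
    re.compile(r"^ZT(?P<time>\d+(?:\.\d+)?)\.(?P<rep>\d+)$"),
)

# fixed, documented column order for per-gene result tables; detectors fill
# the subset that applies to them
RESULT_COLUMNS = (
    "rhythmic", "period", "phase", "amplitude", "mean_level", "pvalue",
    "qvalue", "best_pattern", "best_phase", "correlation", "fold_change",
    "rae",
)


def _fmt_time(t: float) -> str:
    return f"{int(t)}" if float(t).is_integer() else f"{t:g}"


def _parse_header(name: str, line: int):
    for rx in _HEADER_RES:
        m = rx.match(name)
        if m:
            return float(m.group("time")), int(m.group("rep"))
    raise FormatError(f"unparseable sample column name {name!r}", line=line)


def write_expression_matrix(dataset: ExpressionDataset, path) -> None:
    """Write a dataset as gene_id + T<time>_R<rep> tab-delimited columns."""
    cols = {}
    for ti, t in enumerate(dataset.timepoints):
        for r in range(dataset.n_replicates):
            cols[f"T{_fmt_time(t)}_R{r + 1}"] = dataset.values[:, ti, r]
    df = pd.DataFrame(cols, index=pd.Index(dataset.gene_ids, name="gene_id"))
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_expression_matrix(path) -> ExpressionDataset:
    """Parse a tab-delimited expression matrix with replicate columns.

    Raises :class:`FormatError` (naming the offending line) on ragged rows,
    unparseable headers, duplicate gene ids, or an incomplete
    timepoint x replicate grid.  Missing numeric values are kept as NaN;
    downstream detection excludes such genes.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError("expected a gene id column plus sample columns", line=1)
        n_fields = len(header)
        for i, row in enumerate(fh, start=2):
            if row.strip() and len(row.rstrip("\n").split("\t")) != n_fields:
                raise FormatError(
                    f"ragged row: {len(row.rstrip(chr(10)).split(chr(9)))} fields, "
                    f"expected {n_fields}", line=i,
                )
    samples = [_parse_header(c, 1) for c in header[1:]]
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate gene id {dup!r}")
    times = sorted({t for t, _ in samples})
    reps = sorted({r for _, r in samples})
    grid = {(t, r) for t, r in samples}
    want = {(t, r) for t in times for r in reps}
    if grid != want:
        missing = sorted(want - grid)[0]
        raise FormatError(
            f"incomplete replicate grid: no column for time {missing[0]:g} "
            f"replicate {missing[1]}"
        )
    values = np.empty((df.shape[0], len(times), len(reps)))
    for j, (t, r) in enumerate(samples):
        values[:, times.index(t), reps.index(r)] = pd.to_numeric(
            df.iloc[:, j], errors="coerce"
        ).to_numpy()
    return ExpressionDataset(values, np.array(times, float), list(df.index))


def write_truth(labels: TruthLabels, path, gene_params: pd.DataFrame | None = None) -> None:
    """Sidecar truth table: gene_id, rhythmic flag, and, when available,
    the generating period/phase/waveform."""
    if gene_params is not None:
        df = gene_params.set_index("gene_id")
    else:
        df = pd.DataFrame(
            {"rhythmic": labels.rhythmic},
            index=pd.Index(labels.gene_ids, name="gene_id"),
        )
    df.to_csv(path, sep="\t", float_format="%.6g")


def write_results(results: pd.DataFrame, path) -> None:
    """Per-gene detection table, columns in the documented fixed order."""
    cols = [c for c in RESULT_COLUMNS if c in results.columns]
    extra = [c for c in results.columns if c not in RESULT_COLUMNS]
    results.loc[:, cols + extra].to_csv(path, sep="\t", float_format="%.6g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_consensus(table: ConsensusTable, path) -> None:
    """Consensus counts as (gene_id, count, n_datasets) rows."""
    df = pd.DataFrame(
        {
            "count": table.counts,
            "n_datasets": table.n_datasets,
        },
        index=pd.Index(table.gene_ids, name="gene_id"),
    )
    df.to_csv(path, sep="\t")


class RunManifest(BaseModel):
    """Reproducibility record for one CLI run; the pydantic model doubles
    as the manifest's JSON schema."""

    tool: str = "rhythmboot"
    version: str
    command: str
    master_seed: int | None = None
    stage_seeds: dict[str, int | list[int]] = Field(default_factory=dict)
    config: dict = Field(default_factory=dict)
    inputs: dict[str, str] = Field(default_factory=dict)
    outputs: dict[str, str] = Field(default_factory=dict)
    created: str = ""

    @classmethod
    def create(cls, command: str, master_seed=None, **kwargs) -> "RunManifest":
        from . import __version__

        return cls(
            version=__version__,
            command=command,
            master_seed=master_seed,
            created=datetime.now(timezone.utc).isoformat(),
            **kwargs,
        )


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(manifest: RunManifest, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest.model_dump(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> RunManifest:
    """Read and validate a manifest against the schema."""
    with open(path) as fh:
        return RunManifest.model_validate(json.load(fh))
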