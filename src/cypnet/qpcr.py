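"""Dose-response expression datasets and relative fold change.

A dataset holds long-format measurements for one cell line and one gene:
each observation is (dose in nM, replicate index, value).  Dose 0 is the
vehicle control.  Values are either raw qPCR cycle thresholds (Ct, where
one cycle is a factor of two in template abundance, lower Ct = more
transcript) or already-relative expression units.

Two fold-change conventions are supported:

``ddct``
    2^-(Ct - mean vehicle Ct) per replicate — the classic relative
    quantification without a reference gene.  Per-dose mean fold change is
    computed on the log2 (Ct) scale, i.e. it is the geometric mean of the
    replicate fold changes, so the vehicle group's mean is exactly 1.
``ratio``
    value / mean vehicle value for data already on a linear relative
    scale; the vehicle group's (arithmetic) mean is exactly 1.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ArgumentError, ParseError, ValidationError

VALUE_KINDS = ("ct", "relative")


@dataclass(frozen=True)
class Observation:
    dose: float  # nM; 0 = vehicle
    replicate: int
    value: float


@dataclass
class ExpressionDataset:
    """Long-format expression measurements for one cell line and gene."""

    cell_line: str
    gene: str
    observations: list[Observation] = field(default_factory=list)
    value_kind: str = "ct"

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(
                f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}"
            )
        for obs in self.observations:
            if obs.dose < 0:
                raise ValidationError(f"negative dose {obs.dose}")
            if self.value_kind == "ct" and obs.value <= 0:
                raise ValidationError(f"Ct values must be positive, got {obs.value}")

    def doses(self) -> list[float]:
        return sorted({obs.dose for obs in self.observations})

    def groups(self) -> dict[float, np.ndarray]:
        """Observed values grouped by dose, replicate order preserved."""
        out: dict[float, list[float]] = {}
        for obs in self.observations:
            out.setdefault(obs.dose, []).append(obs.value)
        return {d: np.asarray(v, dtype=float) for d, v in sorted(out.items())}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_line": self.cell_line,
                "gene": self.gene,
                "dose_nM": [o.dose for o in self.observations],
                "replicate": [o.replicate for o in self.observations],
                "value": [o.value for o in self.observations],
                "value_kind": self.value_kind,
            }
        )


@dataclass
class FoldChangeTable:
    """Per-dose mean fold change relative to vehicle, replicates retained."""

    cell_line: str
    gene: str
    method: str
    per_dose: pd.DataFrame  # columns: dose_nM, mean_fc, sd_fc, n
    replicates: pd.DataFrame  # columns: dose_nM, replicate, fc

    def groups(self) -> dict[float, np.ndarray]:
        """Per-replicate fold changes grouped by dose (for ANOVA/Tukey)."""
        return {
            float(d): g["fc"].to_numpy()
            for d, g in self.replicates.groupby("dose_nM", sort=True)
        }


def fold_change(ds: ExpressionDataset, method: str = "ddct") -> FoldChangeTable:
    """Relative fold change of each dose group versus the vehicle (dose 0)."""
    if method not in ("ddct", "ratio"):
        raise ArgumentError(f"unknown fold-change method {method!r}")
    groups = ds.groups()
    if 0.0 not in groups:
        raise ArgumentError("no vehicle group (dose 0) in dataset")
    if method == "ddct":
        if ds.value_kind != "ct":
            raise ArgumentError("ddct fold change requires Ct values")
        ref = float(np.mean(groups[0.0]))
        rep_fc = {d: np.exp2(-(v - ref)) for d, v in groups.items()}
        # per-dose mean on the Ct (log2) scale -> geometric mean of replicates
        mean_fc = {d: float(np.exp2(-(np.mean(v) - ref))) for d, v in groups.items()}
    else:
        if ds.value_kind != "relative":
            raise ArgumentError("ratio fold change requires relative values")
        for d, v in groups.items():
            if np.any(v <= 0):
                raise ValidationError(f"non-positive relative value at dose {d}")
        ref = float(np.mean(groups[0.0]))
        rep_fc = {d: v / ref for d, v in groups.items()}
        mean_fc = {d: float(np.mean(v)) for d, v in rep_fc.items()}

    per_dose = pd.DataFrame(
        {
            "dose_nM": list(rep_fc),
            "mean_fc": [mean_fc[d] for d in rep_fc],
            "sd_fc": [
                float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
                for v in rep_fc.values()
            ],
            "n": [len(v) for v in rep_fc.values()],
        }
    )
    replicates = pd.DataFrame(
        [
            {"dose_nM": d, "replicate": i + 1, "fc": float(f)}
            for d, v in rep_fc.items()
            for i, f in enumerate(v)
        ]
    )
    return FoldChangeTable(
        cell_line=ds.cell_line,
        gene=ds.gene,
        method=method,
        per_dose=per_dose,
        replicates=replicates,
    )


# -- long-format TSV I/O ----------------------------------------------------

_EXPR_HEADER = ["cell_line", "gene", "dose_nM", "replicate", "value", "value_kind"]


def read_expression(path: str | Path) -> list[ExpressionDataset]:
    """Read a long-format expression TSV into one dataset per
    (cell_line, gene) pair, in order of first appearance."""
    path = Path(path)
    datasets: dict[tuple[str, str], ExpressionDataset] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty expression file") from None
        if [h.strip().lower() for h in header] != [c.lower() for c in _EXPR_HEADER]:
            raise ParseError(
                f"{path}: expected header {_EXPR_HEADER}, got {header!r}",
                line_number=1,
            )
        for i, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 6:
                raise ParseError(
                    f"{path}: expected 6 columns, got {len(row)}", line_number=i
                )
            cell_line, gene = row[0].strip(), row[1].strip()
            try:
                dose = float(row[2])
                replicate = int(row[3])
                value = float(row[4])
            except ValueError as exc:
                raise ParseError(f"{path}: {exc}", line_number=i) from None
            kind = row[5].strip().lower()
            key = (cell_line, gene)
            if key not in datasets:
                datasets[key] = ExpressionDataset(
                    cell_line=cell_line, gene=gene, value_kind=kind
                )
            ds = datasets[key]
            if kind != ds.value_kind:
                raise ParseError(
                    f"{path}: mixed value_kind for {cell_line}/{gene}",
                    line_number=i,
                )
            ds.observations.append(
                Observation(dose=dose, replicate=replicate, value=value)
            )
    for ds in datasets.values():
        ds.__post_init__()  # re-validate after appends
    return list(datasets.values())


def write_expression(datasets: Iterable[ExpressionDataset], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        fh.write("\t".join(_EXPR_HEADER) + "\n")
        for ds in datasets:
            for obs in ds.observations:
                fh.write(
                    f"{ds.cell_line}\t{ds.gene}\t{obs.dose:g}\t{obs.replicate}\t"
                    f"{float(obs.value)!r}\t{ds.value_kind}\n"
                )
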