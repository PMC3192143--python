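"""Tab-separated readers and writers for the panel formats.

All files are UTF-8 TSV: no quoting ambiguity in instance ids, which are
opaque strings (genomic users may encode intervals like ``chr1:1000-2000``;
no coordinate semantics are parsed).  Both LF and CRLF are accepted on read;
LF is written.  Readers validate eagerly and report the offending row and
column — a silently coerced cell would corrupt every downstream count.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np

from .core import PredictionMatrix
from .scoring import PerformanceEstimate, ValidationOutcomes
from .selection import SelectionPlan

__all__ = [
    "read_predictions",
    "write_predictions",
    "read_outcomes",
    "write_outcomes",
    "write_selection",
    "read_selection",
    "write_scores",
    "write_sidecar",
]


class FormatError(ValueError):
    """A file does not conform to its TSV contract."""


def _read_lines(path: str | os.PathLike) -> list[str]:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        text = fh.read()
    lines = text.replace("\r\n", "\n").replace("\r", "\n").split("\n")
    while lines and lines[-1] == "":
        lines.pop()
    return lines


def read_predictions(path: str | os.PathLike) -> PredictionMatrix:
    """Read a prediction matrix: header ``instance_id<TAB>algo...``, 0/1 cells."""
    lines = _read_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 3 or header[0] != "instance_id":
        raise FormatError(
            f"{path}: header must be 'instance_id<TAB>algo1<TAB>...<TAB>algoM' "
            f"with M >= 2, got {header[:4]}"
        )
    algorithms = header[1:]
    ids: list[str] = []
    seen: set[str] = set()
    rows = np.empty((len(lines) - 1, len(algorithms)), dtype=np.uint8)
    for r, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(
                f"{path}: row {r} has {len(fields)} fields, expected {len(header)}"
            )
        iid = fields[0]
        if iid in seen:
            raise FormatError(f"{path}: duplicate instance id {iid!r} at row {r}")
        seen.add(iid)
        ids.append(iid)
        for c, val in enumerate(fields[1:]):
            if val == "0":
                rows[r - 2, c] = 0
            elif val == "1":
                rows[r - 2, c] = 1
            else:
                raise FormatError(
                    f"{path}: non-binary value {val!r} at row {r}, "
                    f"column {algorithms[c]!r}"
                )
    return PredictionMatrix(
        instance_ids=tuple(ids), algorithm_ids=tuple(algorithms), calls=rows
    )


def write_predictions(pm: PredictionMatrix, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("instance_id\t" + "\t".join(pm.algorithm_ids) + "\n")
        for iid, row in zip(pm.instance_ids, pm.calls):
            fh.write(iid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_outcomes(path: str | os.PathLike) -> ValidationOutcomes:
    """Read validation outcomes: header ``instance_id<TAB>label``, labels 0/1.

    Ids are checked against a prediction matrix at use time, not here.
    """
    lines = _read_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty file")
    if lines[0].split("\t") != ["instance_id", "label"]:
        raise FormatError(f"{path}: header must be 'instance_id<TAB>label'")
    labels: dict[str, int] = {}
    for r, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}: row {r} has {len(fields)} fields, expected 2")
        iid, val = fields
        if iid in labels:
            raise FormatError(f"{path}: duplicate instance id {iid!r} at row {r}")
        if val not in ("0", "1"):
            raise FormatError(f"{path}: label {val!r} at row {r} is not 0/1")
        labels[iid] = int(val)
    return ValidationOutcomes(labels)


def write_outcomes(outcomes: ValidationOutcomes, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("instance_id\tlabel\n")
        for iid, lab in outcomes.labels.items():
            fh.write(f"{iid}\t{lab}\n")


def write_selection(plan: SelectionPlan, path: str | os.PathLike) -> None:
    """Write a plan: rank, instance id, fingerprint string, min Hamming after."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("rank\tinstance_id\tfingerprint\tmin_hamming_after\n")
        for step in plan.steps:
            fp = "".join(str(b) for b in step.fingerprint)
            fh.write(
                f"{step.iteration + 1}\t{step.instance_id}\t{fp}\t"
                f"{step.min_hamming_after}\n"
            )


def read_selection(path: str | os.PathLike) -> list[dict]:
    lines = _read_lines(path)
    header = lines[0].split("\t")
    expected = ["rank", "instance_id", "fingerprint", "min_hamming_after"]
    if header != expected:
        raise FormatError(f"{path}: header must be {expected}")
    out = []
    for line in lines[1:]:
        rank, iid, fp, mh = line.split("\t")
        out.append(
            {
                "rank": int(rank),
                "instance_id": iid,
                "fingerprint": fp,
                "min_hamming_after": int(mh),
            }
        )
    return out


def write_scores(
    estimates: list[PerformanceEstimate], path: str | os.PathLike
) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("algorithm\tauc\tsens\tspec\tn_validated\testimator\tcoverage\n")
        for e in estimates:
            fh.write(
                f"{e.algorithm_id}\t{e.auc:.10g}\t{e.sensitivity:.10g}\t"
                f"{e.specificity:.10g}\t{e.n_validated}\t{e.estimator}\t"
                f"{e.coverage:.10g}\n"
            )


def write_sidecar(config: Mapping[str, object], path: str | os.PathLike) -> None:
    """Key=value metadata file: the effective configuration of a run."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key in sorted(config):
            fh.write(f"{key}={config[key]}\n")
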