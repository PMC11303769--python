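"""End-to-end sex determination: quantify the panel, apply the decision rule,
report per sample and per cohort.

The decision logic follows the presence/absence structure of amelogenin
peptidomics: AmelX-unique peptides occur in enamel of both sexes and act as
the extraction / preservation control, while AmelY-unique peptides occur only
in males. Hence:

* no AmelX marker detected -> indeterminate (enamel recovery failed; absence
  of AmelY evidence means nothing);
* any AmelY marker detected -> male, high confidence when both AmelY markers
  are detected;
* otherwise -> female, high confidence when both AmelX markers are detected.

No intensity-ratio criterion is used; the call is presence/absence at the
configured detection thresholds, which the report echoes in full.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import deamidation as deam
from . import quant
from .panel import MarkerPanel, load_panel
from .quant import MarkerQuantResult, QuantParams
from .spectra import read_run


class WorkflowError(ValueError):
    pass


@dataclass
class SexCall:
    sample_id: str
    call: str  # male | female | indeterminate | failed
    confidence: str  # high | standard
    evidence: dict[str, MarkerQuantResult]
    deamidation: deam.OccupancyResult | None = None
    error: str | None = None


@dataclass
class CohortReport:
    calls: list[SexCall]
    counts: dict[str, int]
    params: dict
    group_comparison: deam.GroupComparison | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            row = {"sample_id": c.sample_id, "call": c.call, "confidence": c.confidence}
            for mid, r in c.evidence.items():
                row[f"{mid}_detected"] = r.detected
                row[f"{mid}_area"] = r.area
                row[f"{mid}_envelope_score"] = round(r.envelope_score, 4)
                row[f"{mid}_ms2_ions"] = r.ms2_matched_ions
            if c.deamidation is not None:
                for cls, v in c.deamidation.occupancy.items():
                    row[f"deamidation_{cls}"] = v
            if c.error:
                row["error"] = c.error
            rows.append(row)
        return pd.DataFrame(rows)


def call_sex(results: dict[str, MarkerQuantResult], panel: MarkerPanel,
             sample_id: str = "") -> SexCall:
    """Apply the AmelX/AmelY presence rule to a full panel of quant results."""
    y_ids = [m.id for m in panel.by_source("AmelY")]
    x_ids = [m.id for m in panel.by_source("AmelX")]
    if not y_ids or not x_ids:
        raise WorkflowError("panel must contain AmelY and AmelX markers")
    missing = [mid for mid in y_ids + x_ids if mid not in results]
    if missing:
        raise WorkflowError(f"quantification missing for markers: {missing}")

    y_detected = [mid for mid in y_ids if results[mid].detected]
    x_detected = [mid for mid in x_ids if results[mid].detected]

    if not x_detected:
        call, confidence = "indeterminate", "standard"
    elif y_detected:
        call = "male"
        confidence = "high" if len(y_detected) == len(y_ids) else "standard"
    else:
        call = "female"
        confidence = "high" if len(x_detected) == len(x_ids) else "standard"
    return SexCall(sample_id=sample_id, call=call, confidence=confidence,
                   evidence=dict(results))


def quantify_sample(run, panel: MarkerPanel, params: QuantParams | None = None,
                    background_peptides=None) -> SexCall:
    """Quantify all panel markers in one run and call its sex."""
    params = params or QuantParams()
    results = {m.id: quant.quantify_marker(run, m, params) for m in panel}
    call = call_sex(results, panel, sample_id=run.sample_id)
    if background_peptides:
        call.deamidation = deam.occupancy_from_run(run, background_peptides, params)
    return call


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Manifest TSV: sample_id, path, optional group (modern|archaeological)
    and known_sex columns."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty:
        raise WorkflowError(f"empty manifest: {path}")
    for col in ("sample_id", "path"):
        if col not in df.columns:
            raise WorkflowError(f"manifest lacks required column {col!r}")
    return df


def run_pipeline(
    manifest: pd.DataFrame,
    panel: MarkerPanel | None = None,
    params: QuantParams | None = None,
    background_peptides=None,
    base_dir: str | Path | None = None,
) -> CohortReport:
    """Quantify and classify every run in a manifest.

    An unreadable run flags its row as failed and the pipeline continues; if
    every run fails the pipeline errors out. When group labels and background
    peptides are supplied, a modern-vs-archaeological deamidation comparison
    is appended.
    """
    panel = panel or load_panel()
    params = params or QuantParams()
    if manifest.empty:
        raise WorkflowError("empty manifest")

    calls: list[SexCall] = []
    for _, row in manifest.iterrows():
        path = Path(row["path"])
        if base_dir is not None and not path.is_absolute():
            path = Path(base_dir) / path
        try:
            run = read_run(path)
            call = quantify_sample(run, panel, params, background_peptides)
            call.sample_id = str(row["sample_id"])
        except Exception as exc:  # noqa: BLE001 - per-row fault isolation
            call = SexCall(sample_id=str(row["sample_id"]), call="failed",
                           confidence="standard", evidence={}, error=str(exc))
        calls.append(call)

    if all(c.call == "failed" for c in calls):
        raise WorkflowError("all runs failed to process")

    counts: dict[str, int] = {}
    for c in calls:
        counts[c.call] = counts.get(c.call, 0) + 1

    comparison = None
    if "group" in manifest.columns and background_peptides:
        by_group: dict[str, list[deam.OccupancyResult]] = {}
        for c, (_, row) in zip(calls, manifest.iterrows()):
            if c.deamidation is not None:
                by_group.setdefault(str(row["group"]), []).append(c.deamidation)
        if "modern" in by_group and "archaeological" in by_group:
            comparison = deam.compare_groups(by_group["modern"],
                                             by_group["archaeological"])

    return CohortReport(calls=calls, counts=counts,
                        params={k: v for k, v in vars(params).items()},
                        group_comparison=comparison)


def report_json(report: CohortReport) -> str:
    payload = {
        "counts": report.counts,
        "params": report.params,
        "calls": [
            {"sample_id": c.sample_id,
             "call": c.call, "confidence": c.confidence,
             "detected": {mid: r.detected for mid, r in c.evidence.items()},
             "areas": {mid: r.area for mid, r in c.evidence.items()},
             "deamidation": (c.deamidation.occupancy if c.deamidation else None),
             "error": c.error}
            for c in report.calls
        ],
    }
    if report.group_comparison is not None:
        payload["deamidation_fold_change"] = report.group_comparison.fold_change
        payload["deamidation_group_means"] = {
            "modern": report.group_comparison.mean_a,
            "archaeological": report.group_comparison.mean_b,
        }
    return json.dumps(payload, indent=2, default=str)
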