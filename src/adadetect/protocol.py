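"""Certification exams and the deployment scan.

A trained detective qualifies through two exams on a known shortcut-free
labeled dataset:

* **Exam 1** — scored as-is.  The detective must NOT separate the classes:
  AUC within ``tau1`` of 0.5.  This guards against the detective's features
  being entangled with the original labeling.
* **Exam 2a / 2b** — the detective's own attribute perturbation is injected
  into the positive (2a) or negative (2b) class of the same shortcut-free
  base.  The detective must separate near-perfectly: AUC at least
  ``1 - tau2`` (2a) and at most ``tau2`` (2b).  The 2b extreme is 0 rather
  than 1 purely because of label orientation.

Only detectives holding a passing certification may be deployed.
:func:`scan_dataset` refuses uncertified detectives outright — the central
safety contract: a verdict is only meaningful from a scorer known to react to
its attribute and to nothing else.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .datasets import LabeledDataset, inject_into_class
from .detective import Detective, score
from .metrics import AUCResult, bootstrap_ci

#: Exam-1 tolerance around chance level
DEFAULT_TAU1 = 0.07
#: Exam-2 tolerance from the extremes (1.0 and 0.0)
DEFAULT_TAU2 = 0.01
#: deployment effect-size threshold on |AUC - 0.5|
DEFAULT_DELTA = 0.10


def _exam_auc(
    detective: Detective,
    dataset: LabeledDataset,
    replicates: int,
    seed: int,
) -> AUCResult:
    dataset.require_both_classes()
    scores = score(detective, dataset.images)
    return bootstrap_ci(scores, dataset.labels, replicates=replicates, seed=seed)


def run_exam1(
    detective: Detective,
    shortcut_free: LabeledDataset,
    tau1: float = DEFAULT_TAU1,
    replicates: int = 2000,
    seed: int = 0,
) -> tuple[AUCResult, bool]:
    """Exam 1: chance-level AUC required on a shortcut-free dataset."""
    if shortcut_free.injected_ada is not None:
        raise ValueError(
            "Exam 1 requires a shortcut-free dataset; "
            f"{shortcut_free.name!r} carries an injection"
        )
    result = _exam_auc(detective, shortcut_free, replicates, seed)
    return result, abs(result.auc - 0.5) <= tau1


def run_exam2(
    detective: Detective,
    base: LabeledDataset,
    target_label: int,
    tau2: float = DEFAULT_TAU2,
    replicates: int = 2000,
    seed: int = 0,
) -> tuple[AUCResult, bool]:
    """Exam 2: near-perfect AUC required after injecting the detective's ADA.

    ``target_label=1`` expects AUC >= 1 - tau2; ``target_label=0`` expects
    AUC <= tau2 (same separation, opposite label orientation).
    """
    if base.injected_ada is not None:
        raise ValueError(
            f"Exam 2 base must be shortcut-free; {base.name!r} carries an injection"
        )
    if detective.ada is None:
        raise ValueError("detective carries no ADA spec; cannot run Exam 2")
    injected = inject_into_class(base, detective.ada, target_label)
    result = _exam_auc(detective, injected, replicates, seed)
    passed = (
        result.auc >= 1.0 - tau2 if target_label == 1 else result.auc <= tau2
    )
    return result, passed


@dataclass
class CertificationReport:
    """Outcome of the two-exam protocol for one detective."""

    exam1: AUCResult
    exam2a: AUCResult
    exam2b: AUCResult
    tau1: float
    tau2: float
    passed: bool
    dataset_name: str
    detective_fingerprint: str

    def to_dict(self) -> dict:
        return {
            "exam1": self.exam1.to_dict(),
            "exam2a": self.exam2a.to_dict(),
            "exam2b": self.exam2b.to_dict(),
            "tau1": self.tau1,
            "tau2": self.tau2,
            "passed": self.passed,
            "dataset_name": self.dataset_name,
            "detective_fingerprint": self.detective_fingerprint,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CertificationReport":
        return cls(
            exam1=AUCResult.from_dict(d["exam1"]),
            exam2a=AUCResult.from_dict(d["exam2a"]),
            exam2b=AUCResult.from_dict(d["exam2b"]),
            tau1=d["tau1"],
            tau2=d["tau2"],
            passed=d["passed"],
            dataset_name=d["dataset_name"],
            detective_fingerprint=d["detective_fingerprint"],
        )

    def format(self) -> str:
        lines = [
            f"Certification on {self.dataset_name}",
            f"  Exam 1  (shortcut-free):      {self.exam1.format()}"
            f"   [need |AUC-0.5| <= {self.tau1:g}]",
            f"  Exam 2a (ADA into label 1):   {self.exam2a.format()}"
            f"   [need AUC >= {1 - self.tau2:g}]",
            f"  Exam 2b (ADA into label 0):   {self.exam2b.format()}"
            f"   [need AUC <= {self.tau2:g}]",
            f"  -> {'CERTIFIED' if self.passed else 'NOT CERTIFIED'}",
        ]
        return "\n".join(lines)


def certify(
    detective: Detective,
    shortcut_free: LabeledDataset,
    tau1: float = DEFAULT_TAU1,
    tau2: float = DEFAULT_TAU2,
    replicates: int = 2000,
    seed: int = 0,
) -> CertificationReport:
    """Run all three exams, stamp the detective, return the report.

    All exams always run (no short-circuit) so the report is complete;
    ``passed`` is the conjunction of the three pass flags.
    """
    r1, p1 = run_exam1(detective, shortcut_free, tau1, replicates, seed)
    r2a, p2a = run_exam2(detective, shortcut_free, 1, tau2, replicates, seed)
    r2b, p2b = run_exam2(detective, shortcut_free, 0, tau2, replicates, seed)
    report = CertificationReport(
        exam1=r1,
        exam2a=r2a,
        exam2b=r2b,
        tau1=tau1,
        tau2=tau2,
        passed=p1 and p2a and p2b,
        dataset_name=shortcut_free.name,
        detective_fingerprint=detective.fingerprint(),
    )
    detective.certification = report.to_dict()
    return report


class UncertifiedDetectiveError(RuntimeError):
    """Raised when an uncertified detective is offered for deployment."""


@dataclass
class ScanReport:
    """Per-attribute audit verdicts for one labeled dataset."""

    dataset_name: str
    delta: float
    entries: list[dict]  # {ada, auc (AUCResult dict), verdict, fingerprint}

    @property
    def any_shortcut(self) -> bool:
        return any(e["verdict"] == "shortcut_detected" for e in self.entries)

    def to_dict(self) -> dict:
        return {
            "dataset_name": self.dataset_name,
            "delta": self.delta,
            "entries": self.entries,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def format(self) -> str:
        lines = [f"Scan of {self.dataset_name} (delta={self.delta:g})"]
        for e in self.entries:
            auc = AUCResult.from_dict(e["auc"])
            lines.append(f"  {e['ada']:<34} {auc.format()}   {e['verdict']}")
        return "\n".join(lines)


def scan_dataset(
    detectives: list[Detective],
    dataset: LabeledDataset,
    delta: float = DEFAULT_DELTA,
    replicates: int = 2000,
    seed: int = 0,
) -> ScanReport:
    """Audit a labeled dataset with certified detectives.

    Verdict per detective: ``shortcut_detected`` iff ``|AUC - 0.5| > delta``
    AND the bootstrap CI excludes 0.5 — an effect-size condition joined with a
    significance condition, so large datasets cannot flag trivially small
    deviations.  Raises :class:`UncertifiedDetectiveError` (before any
    scoring) if any offered detective lacks a passing certification.
    """
    for i, det in enumerate(detectives):
        if not det.is_certified:
            name = det.ada.describe() if det.ada else f"detective #{i}"
            raise UncertifiedDetectiveError(
                f"refusing to scan with uncertified detective: {name}"
            )
    dataset.require_both_classes()
    entries = []
    for det in detectives:
        result = _exam_auc(det, dataset, replicates, seed)
        deviates = abs(result.auc - 0.5) > delta
        significant = result.ci_low > 0.5 or result.ci_high < 0.5
        verdict = (
            "shortcut_detected" if deviates and significant
            else "no_shortcut_detected"
        )
        entries.append({
            "ada": det.ada.describe() if det.ada else "unknown",
            "auc": result.to_dict(),
            "verdict": verdict,
            "fingerprint": det.fingerprint(),
        })
    return ScanReport(dataset_name=dataset.name, delta=delta, entries=entries)
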