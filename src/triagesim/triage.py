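"""Triage decision tree: tool classification, destination and secondary transfer.

A patient's pathway is determined in two steps. The triage tool (plus
paramedic judgement) classifies the patient positive with probability equal
to the tool's sensitivity if their ISS is >= 16 and to one minus its
specificity otherwise. The secondary-transfer step then applies
category-specific probabilities: tool-negative patients start at a local
hospital and may be transferred onwards to an MTC; tool-positive patients
are MTC patients, but with the true/false-positive transfer probability they
are first taken to the local hospital for urgent stabilisation and then
transferred (receiving the full MTC benefit and incurring the transfer
cost).

All randomness enters through caller-supplied uniform draws so that the
same patient-level draws can be reused across every tool under comparison
(common random numbers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import TransferProbs, TriageTool

__all__ = ["Pathway", "classify", "assign_pathway", "expected_flows",
           "classify_vec", "assign_pathway_vec"]


@dataclass(frozen=True)
class Pathway:
    """Where one patient was treated."""

    tool_positive: bool
    local_first: bool   # started at a local hospital (incl. positives stabilised locally)
    transferred: bool   # a local -> MTC transfer occurred
    ever_mtc: bool      # received MTC care at some point

    def __post_init__(self) -> None:
        if self.transferred and not self.ever_mtc:
            raise ValueError("transferred implies ever_mtc")
        if self.tool_positive and not self.ever_mtc:
            raise ValueError("tool-positive implies ever_mtc")
        if not self.tool_positive and not self.transferred and self.ever_mtc:
            raise ValueError("tool-negative, untransferred patients never reach an MTC")


def classify(iss_ge16: bool, tool: TriageTool, u: float) -> bool:
    """Tool-positive decision from one uniform draw.

    P(positive | ISS >= 16) = sensitivity; P(positive | ISS < 16) = 1 - specificity.
    Sharing ``u`` across tools makes positives nest as sensitivity rises.
    """
    if not 0.0 <= u < 1.0:
        raise ValueError("u must be in [0, 1)")
    threshold = tool.sensitivity if iss_ge16 else 1.0 - tool.specificity
    return u < threshold


def assign_pathway(tool_positive: bool, iss_ge16: bool,
                   transfers: TransferProbs, u: float) -> Pathway:
    """Destination and secondary-transfer outcome from one uniform draw."""
    if not 0.0 <= u < 1.0:
        raise ValueError("u must be in [0, 1)")
    if tool_positive:
        p = transfers.tp if iss_ge16 else transfers.fp
        stabilised_locally = u < p
        return Pathway(True, stabilised_locally, stabilised_locally, True)
    p = transfers.fn if iss_ge16 else transfers.tn
    transferred = u < p
    return Pathway(False, True, transferred, transferred)


def classify_vec(iss_ge16: np.ndarray, tool: TriageTool,
                 u: np.ndarray) -> np.ndarray:
    """Vectorised :func:`classify` over a cohort."""
    threshold = np.where(iss_ge16, tool.sensitivity, 1.0 - tool.specificity)
    return u < threshold


def assign_pathway_vec(tool_positive: np.ndarray, iss_ge16: np.ndarray,
                       transfers: TransferProbs, u: np.ndarray):
    """Vectorised :func:`assign_pathway`.

    Returns ``(local_first, transferred, ever_mtc)`` boolean arrays.
    """
    p = np.where(tool_positive,
                 np.where(iss_ge16, transfers.tp, transfers.fp),
                 np.where(iss_ge16, transfers.fn, transfers.tn))
    moved = u < p
    transferred = moved  # for positives this is the stabilise-then-transfer branch
    local_first = np.where(tool_positive, moved, True)
    ever_mtc = tool_positive | transferred
    return local_first, transferred, ever_mtc


def expected_flows(tool: TriageTool, n_iss16: float, n_issLT16: float,
                   transfers: TransferProbs) -> pd.Series:
    """Analytic expected patient flows (no simulation).

    Expected number of patients who ever reach an MTC, by severity group:
    an ISS >= 16 patient reaches an MTC if triaged positive (sensitivity) or,
    if negative, via a false-negative transfer; an ISS < 16 patient if triaged
    positive (1 - specificity) or via a true-negative transfer.
    """
    if n_iss16 < 0 or n_issLT16 < 0:
        raise ValueError("counts must be non-negative")
    sens, spec = tool.sensitivity, tool.specificity
    mtc_iss16 = n_iss16 * (sens + (1.0 - sens) * transfers.fn)
    mtc_issLT16 = n_issLT16 * ((1.0 - spec) + spec * transfers.tn)
    return pd.Series({
        "label": tool.label,
        "sensitivity": sens,
        "specificity": spec,
        "mtc_total": mtc_iss16 + mtc_issLT16,
        "mtc_iss16": mtc_iss16,
        "mtc_issLT16": mtc_issLT16,
    })
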