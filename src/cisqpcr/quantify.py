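"""Two-color Cq measurements -> absolute molecule counts.

The core arithmetic of competitive internal-standard qPCR: in every well the
native template (NT, one fluorescence channel) and a known number of internal
standard molecules (IS, the other channel) are co-amplified with shared
primers, so interference, efficiency and loading cancel in the Cq difference

    raw dCq       = NT Cq - IS Cq
    corrected dCq = raw dCq - ESM offset          (per run, per gene)
    NT copies     = IS copies * 2**(-corrected dCq)

where the ESM offset is the mean NT-IS Cq difference of external-standard
wells containing a 1:1 NT/IS mixture (expected difference zero; anything else
is channel-intensity or threshold drift).  Target genes are reported per 1e6
reference-gene molecules.

An undetermined Cq is an explicit sentinel (NaN in tables, None in scalars),
never a magic cycle number.  Call logic guarantees no false negatives: a well
whose IS channel failed is an assay failure, never a zero.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InvalidInputError,
    MissingCalibrationError,
    ReferenceFailureError,
)
from .standards import StandardsMix, round_sig

# ---------------------------------------------------------------------------
# statuses

QUANTIFIABLE = "quantifiable"
GATED_OUT = "gated_out"
TARGET_NOT_DETECTED = "target_not_detected"
ASSAY_FAILED = "assay_failed"

#: Well roles in the plate layout.
ROLE_SAMPLE = "sample"
ROLE_ESM = "esm"
ROLE_NTC = "ntc"

WELL_COLUMNS = ["plate_id", "well_id", "sample_id", "role", "ism_id", "gene", "nt_cq", "is_cq"]


def is_determined(cq) -> bool:
    """True when a Cq value is an actual number (not the undetermined sentinel)."""
    if cq is None:
        return False
    try:
        return not math.isnan(float(cq))
    except (TypeError, ValueError):
        return False


@dataclass(frozen=True)
class TwoColorWell:
    """One PCR well: both channel Cq values plus plate bookkeeping."""

    plate_id: str
    well_id: str
    sample_id: str
    gene: str
    role: str = ROLE_SAMPLE
    ism_id: str | None = None
    nt_cq: float | None = None
    is_cq: float | None = None


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean / sample SD / CV of replicate measurements."""

    sample_id: str
    gene: str
    n: int
    mean: float
    sd: float | None
    cv: float | None


# ---------------------------------------------------------------------------
# scalar operations


def raw_delta_cq(nt_cq: float, is_cq: float) -> float:
    """NT Cq minus IS Cq.  Both values must be determined."""
    if not (is_determined(nt_cq) and is_determined(is_cq)):
        raise InvalidInputError(
            "raw_delta_cq requires determined Cq in both channels; "
            "route undetermined wells through classify_well"
        )
    return float(nt_cq) - float(is_cq)


def esm_offset(esm_wells: Iterable) -> float:
    """Mean NT-IS Cq difference over the external-standard wells of one gene.

    Accepts :class:`TwoColorWell` records or any objects/rows exposing
    ``nt_cq`` and ``is_cq``.  Wells with an undetermined channel are skipped;
    if none remain a :class:`MissingCalibrationError` is raised so that
    quantification cannot silently proceed uncalibrated.
    """
    deltas = []
    for w in esm_wells:
        nt = w["nt_cq"] if isinstance(w, (dict, pd.Series)) else w.nt_cq
        is_ = w["is_cq"] if isinstance(w, (dict, pd.Series)) else w.is_cq
        if is_determined(nt) and is_determined(is_):
            deltas.append(float(nt) - float(is_))
    if not deltas:
        raise MissingCalibrationError("no external-standard well with both channels determined")
    return float(np.mean(deltas))


def copies_from_cq(
    nt_cq: float,
    is_cq: float,
    offset: float,
    is_copies: float,
    report_sig_figs: int | None = None,
) -> float:
    """NT molecules per reaction from a Cq pair, an ESM offset and known IS input.

    ``report_sig_figs`` rounds for presentation only (2 reproduces published
    table formatting); internal consumers always pass None.
    """
    if is_copies <= 0:
        raise InvalidInputError(f"is_copies must be > 0, got {is_copies}")
    corrected = raw_delta_cq(nt_cq, is_cq) - offset
    copies = is_copies * 2.0 ** (-corrected)
    if report_sig_figs is not None:
        copies = round_sig(copies, report_sig_figs)
    return copies


def normalize_to_reference(target_copies: float, ref_copies: float) -> float:
    """Target molecules per 1e6 reference-gene molecules."""
    if ref_copies <= 0:
        raise ReferenceFailureError(
            f"reference copies must be > 0 (got {ref_copies}); sample not reportable"
        )
    if target_copies < 0:
        raise InvalidInputError("target_copies must be >= 0")
    return target_copies / ref_copies * 1e6


def ratio_gate(corrected_delta_cq: float, fold_limit: float = 10.0) -> bool:
    """True when the NT:IS ratio lies within [1/fold_limit, fold_limit].

    Measurements outside a ten-fold NT:IS imbalance lose linearity, so the
    published procedure restricts reporting to this window.  Boundary values
    pass (inclusive semantics, with a small numeric tolerance so that
    dCq == log2(fold_limit) passes exactly).
    """
    if fold_limit <= 1:
        raise InvalidInputError("fold_limit must be > 1")
    return abs(corrected_delta_cq) <= math.log2(fold_limit) + 1e-12


def classify_well(nt_cq, is_cq) -> str:
    """Call status from the two channels.

    - both determined            -> quantifiable
    - NT missing, IS determined  -> target_not_detected (a true negative: the
      IS amplified, so the reaction worked and the target is below detection)
    - IS missing                 -> assay_failed (interference or reaction
      failure; never reported as a zero — this is the no-false-negative rule)
    """
    if is_determined(is_cq):
        return QUANTIFIABLE if is_determined(nt_cq) else TARGET_NOT_DETECTED
    return ASSAY_FAILED


def summarize_replicates(values: Sequence[float], sample_id: str = "", gene: str = "") -> ReplicateSummary:
    """Mean, sample SD (n-1 denominator) and CV of replicate quantities."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise InvalidInputError("summarize_replicates requires at least one value")
    mean = float(np.mean(vals))
    if vals.size >= 2:
        sd = float(np.std(vals, ddof=1))
        cv = sd / mean if mean != 0 else None
    else:
        sd = None
        cv = None
    return ReplicateSummary(sample_id=sample_id, gene=gene, n=int(vals.size), mean=mean, sd=sd, cv=cv)


# ---------------------------------------------------------------------------
# table-level pipeline


def esm_offsets(
    wells: pd.DataFrame, pooling: str = "per_plate"
) -> pd.Series:
    """ESM offsets per gene from the calibrator wells of a run table.

    ``pooling="per_plate"`` (default) computes one offset per (plate, gene),
    matching per-run calibration; ``"pooled"`` averages across plates.  The
    returned Series is indexed by (plate_id, gene) or gene respectively.
    """
    esm = wells[wells["role"] == ROLE_ESM]
    usable = esm[esm["nt_cq"].notna() & esm["is_cq"].notna()]
    if pooling == "per_plate":
        keys = ["plate_id", "gene"]
    elif pooling == "pooled":
        keys = ["gene"]
    else:
        raise InvalidInputError(f"unknown pooling mode {pooling!r}")
    if usable.empty:
        return pd.Series(dtype=float)
    return (usable["nt_cq"] - usable["is_cq"]).groupby([usable[k] for k in keys]).mean()


def quantify_wells(
    wells: pd.DataFrame,
    catalog: Mapping[str, StandardsMix],
    *,
    esm_correction: bool = True,
    offset_pooling: str = "per_plate",
    fold_limit: float = 10.0,
) -> pd.DataFrame:
    """Quantify every sample well of a run table.

    Returns one row per sample well with raw/corrected dCq, the applied ESM
    offset, IS and NT copies and the gate/call status.  Gated-out wells keep
    their computed value for diagnostics; downstream summaries exclude them.
    With ``esm_correction=False`` the offset is zero for every well (the
    uncorrected mode used to demonstrate inter-run drift).
    """
    missing = [c for c in WELL_COLUMNS if c not in wells.columns]
    if missing:
        raise InvalidInputError(f"wells table lacks columns: {missing}")
    offsets = esm_offsets(wells, offset_pooling) if esm_correction else None

    records = []
    samples = wells[wells["role"] == ROLE_SAMPLE]
    for _, w in samples.iterrows():
        status = classify_well(w["nt_cq"], w["is_cq"])
        rec = {
            "plate_id": w["plate_id"],
            "well_id": w["well_id"],
            "sample_id": w["sample_id"],
            "gene": w["gene"],
            "status": status,
            "raw_delta_cq": np.nan,
            "esm_offset": np.nan,
            "corrected_delta_cq": np.nan,
            "is_copies": np.nan,
            "nt_copies": np.nan,
        }
        if status == QUANTIFIABLE:
            mix = catalog.get(w["ism_id"])
            if mix is None:
                raise InvalidInputError(
                    f"well {w['plate_id']}/{w['well_id']}: unknown ISM {w['ism_id']!r}"
                )
            if esm_correction:
                key = (w["plate_id"], w["gene"]) if offset_pooling == "per_plate" else w["gene"]
                if key not in offsets.index:
                    raise MissingCalibrationError(
                        f"no usable ESM well for gene {w['gene']!r} "
                        f"(plate {w['plate_id']!r}, pooling={offset_pooling})"
                    )
                offset = float(offsets.loc[key])
            else:
                offset = 0.0
            raw = raw_delta_cq(w["nt_cq"], w["is_cq"])
            corrected = raw - offset
            is_copies = mix.is_copies(w["gene"])
            rec.update(
                raw_delta_cq=raw,
                esm_offset=offset,
                corrected_delta_cq=corrected,
                is_copies=is_copies,
                nt_copies=is_copies * 2.0 ** (-corrected),
            )
            if not ratio_gate(corrected, fold_limit):
                rec["status"] = GATED_OUT
        records.append(rec)
    return pd.DataFrame.from_records(records)


def normalize_results(
    quant: pd.DataFrame,
    reference_gene: str = "ACTB",
    *,
    include_gated: bool = False,
) -> pd.DataFrame:
    """Attach per-1e6-reference values to target-gene quantification rows.

    Each target well is normalized by the mean reference-gene NT copies of the
    same sample on the same plate (one PCR run normalizes against its own
    loading control).  When the reference is not quantifiable on that plate,
    ``reference_ok`` is False and ``per_million_ref`` stays NaN for every
    target of that sample/plate — the sample is not reportable there.
    """
    ok_status = {QUANTIFIABLE, GATED_OUT} if include_gated else {QUANTIFIABLE}
    ref = quant[(quant["gene"] == reference_gene) & (quant["status"].isin(ok_status))]
    ref_means = ref.groupby(["plate_id", "sample_id"])["nt_copies"].mean()

    out = quant[quant["gene"] != reference_gene].copy()
    per_million = np.full(len(out), np.nan)
    reference_ok = np.zeros(len(out), dtype=bool)
    for i, (_, row) in enumerate(out.iterrows()):
        key = (row["plate_id"], row["sample_id"])
        if key in ref_means.index and ref_means.loc[key] > 0:
            reference_ok[i] = True
            if row["status"] in ok_status:
                per_million[i] = normalize_to_reference(row["nt_copies"], ref_means.loc[key])
            elif row["status"] == TARGET_NOT_DETECTED:
                per_million[i] = 0.0
    out["per_million_ref"] = per_million
    out["reference_ok"] = reference_ok
    return out


def summarize_expression(normalized: pd.DataFrame) -> pd.DataFrame:
    """Per sample x gene replicate summary (n, mean, sd, cv) of normalized values.

    Only quantifiable, reference-backed replicates enter the clinical summary;
    gated-out wells are excluded by design (their values remain in the per-well
    table for audit).
    """
    usable = normalized[
        (normalized["status"] == QUANTIFIABLE) & normalized["reference_ok"]
    ]
    rows = []
    for (sample, gene), grp in usable.groupby(["sample_id", "gene"], sort=False):
        s = summarize_replicates(grp["per_million_ref"].to_numpy(), sample, gene)
        rows.append(
            {"sample_id": sample, "gene": gene, "n": s.n, "mean": s.mean, "sd": s.sd, "cv": s.cv}
        )
    return pd.DataFrame(rows, columns=["sample_id", "gene", "n", "mean", "sd", "cv"])
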