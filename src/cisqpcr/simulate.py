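"""Mechanistic simulator of two-color competitive PCR.

Generates the same wells tables the quantification pipeline consumes, with
known ground truth.  The model is deliberately minimal but mechanistic:

- Amplification: per cycle every template in a well grows by a shared
  effective efficiency  e_c = e0 * hill(inhibitor) * max(0, 1 - total/capacity),
  i.e. logistic saturation against a single reagent capacity shared by all
  amplicons in the well.  Because native template (NT) and internal standard
  (IS) share primer sites, they always share e_c — the NT/IS ratio is
  conserved through any interference, which is the premise that makes
  competitive quantification work.
- Workflow: a multiplexed low-cycle pre-amplification of all genes plus the
  ISM, a large dilution, then a per-gene probed second round.
- Detection: channel fluorescence is proportional to amplicon copies times a
  per-channel scale and a run-level lognormal drift; Cq is the fractional
  cycle where fluorescence crosses the run threshold (log-linear
  interpolation), or undetermined if it never does within the cycle budget.
  Per-well Gaussian Cq jitter models instrument noise.
- Optional Poisson draws of input copies reproduce limiting-dilution
  stochasticity at low copy number.

Randomness: one root seed; every reaction and well derives its substream
from a stable hash of (seed, plate, well), so any well is reproducible in
isolation and outputs are byte-identical across runs.
"""
from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError
from .standards import (
    DEFAULT_ESM_LEVELS,
    DEFAULT_GENES,
    DEFAULT_REFERENCE,
    StandardsMix,
    default_catalog,
    default_esm_mixes,
    make_esm,
    make_ism,
    molar_to_copies,
)

WELL_COLUMNS = ["plate_id", "well_id", "sample_id", "role", "ism_id", "gene", "nt_cq", "is_cq"]


@dataclass(frozen=True)
class SimConfig:
    """Simulator parameters.

    e0 : base per-cycle amplification efficiency (1.0 = perfect doubling).
    capacity : amplicon copies at plateau, shared by all templates in a well.
    preamp_cycles / second_cycles : cycle counts of the two PCR rounds.
    dilution_factor : net fold reduction of material between rounds
        (dilution of the first-round product times the carried-over volume
        fraction; 20000 models a 1000-fold dilution of which 1/20 of a
        reaction volume is carried forward).
    fluor_scale_nt / fluor_scale_is : fluorescence per molecule and channel.
    fluor_run_sd : sd of the per-run lognormal intensity drift (per channel).
    cq_noise_sd : per-well Gaussian Cq jitter, in cycles.
    threshold_mode : "fixed_fraction" uses threshold_fraction * capacity;
        "baseline_sd" additionally applies a per-run lognormal threshold
        drift (threshold_drift_sd), emulating auto-threshold variation.
    inhibitor_ic50 / inhibitor_hill : Hill dose-response of an interfering
        substance (mM); efficiency is multiplied by 1/(1 + (d/ic50)**hill).
    poisson_input : draw input copies as Poisson variates (limiting dilution).
    """

    e0: float = 0.95
    capacity: float = 1e11
    preamp_cycles: int = 18
    second_cycles: int = 40
    dilution_factor: float = 20000.0
    fluor_scale_nt: float = 1.0
    fluor_scale_is: float = 1.0
    fluor_run_sd: float = 0.1
    cq_noise_sd: float = 0.1
    threshold_mode: str = "fixed_fraction"
    threshold_fraction: float = 1e-3
    threshold_drift_sd: float = 0.3
    inhibitor_ic50: float = 3.0
    inhibitor_hill: float = 8.0
    poisson_input: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.e0 <= 1:
            raise InvalidInputError("e0 must lie in (0, 1]")
        if self.capacity <= 0 or self.dilution_factor <= 0:
            raise InvalidInputError("capacity and dilution_factor must be > 0")
        for name in ("fluor_run_sd", "cq_noise_sd", "threshold_drift_sd"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        if self.threshold_mode not in ("fixed_fraction", "baseline_sd"):
            raise InvalidInputError(f"unknown threshold_mode {self.threshold_mode!r}")


@dataclass(frozen=True)
class CohortSpec:
    """FFPE-like cohort generator parameters.

    Expression medians are per 1e6 reference molecules; spread is geometric
    (lognormal).  ``actb_median`` sets absolute loading-control molecules per
    reaction, which converts relative expression into input copy numbers.
    """

    n_benign: int = 10
    n_malignant: int = 10
    benign_medians: Mapping[str, float] = field(
        default_factory=lambda: {"MYC": 1.0e4, "E2F1": 1.9e3, "CDKN1A": 4.0e4}
    )
    malignant_medians: Mapping[str, float] = field(
        default_factory=lambda: {"MYC": 1.1e4, "E2F1": 5.1e3, "CDKN1A": 3.1e4}
    )
    gsd: float = 1.5
    actb_median: float = 7e5
    actb_gsd: float = 1.5
    replicates: int = 3
    ism_id: str = "ISM-D"

    def __post_init__(self) -> None:
        if self.n_benign < 0 or self.n_malignant < 0:
            raise InvalidInputError("cohort sizes must be >= 0")
        if self.gsd < 1 or self.actb_gsd < 1:
            raise InvalidInputError("geometric sd must be >= 1")


def _stable_seed(seed: int, *parts: str) -> int:
    """Deterministic 31-bit substream seed from the root seed and a label path."""
    label = "|".join(str(p) for p in parts)
    return zlib.crc32(f"{seed}|{label}".encode()) & 0x7FFFFFFF


def hill_response(dose_mM: float, cfg: SimConfig) -> float:
    """Fractional efficiency retained at an inhibitor dose (Hill curve)."""
    if dose_mM < 0:
        raise InvalidInputError("inhibitor dose must be >= 0")
    if dose_mM == 0:
        return 1.0
    return 1.0 / (1.0 + (dose_mM / cfg.inhibitor_ic50) ** cfg.inhibitor_hill)


def amplify_multi(
    n0: Sequence[float], cycles: int, cfg: SimConfig, inhibitor_mM: float = 0.0
) -> np.ndarray:
    """Co-amplify several templates sharing one capacity; returns (cycles+1, k)."""
    n = np.asarray(n0, dtype=float)
    if np.any(n < 0):
        raise InvalidInputError("initial copies must be >= 0")
    inhib = hill_response(inhibitor_mM, cfg)
    traj = np.empty((cycles + 1, n.size))
    traj[0] = n
    for c in range(cycles):
        e = cfg.e0 * inhib * max(0.0, 1.0 - traj[c].sum() / cfg.capacity)
        traj[c + 1] = traj[c] * (1.0 + e)
    return traj


def amplify(
    n0_nt: float, n0_is: float, cycles: int, cfg: SimConfig, inhibitor_mM: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle NT and IS copy trajectories in one two-template reaction."""
    traj = amplify_multi([n0_nt, n0_is], cycles, cfg, inhibitor_mM)
    return traj[:, 0], traj[:, 1]


def call_cq(
    trajectory: np.ndarray,
    cfg: SimConfig,
    scale: float = 1.0,
    drift: float = 1.0,
    threshold: float | None = None,
) -> float | None:
    """Fractional threshold-crossing cycle of a fluorescence trace, or None.

    Fluorescence is ``scale * drift * copies``; the crossing cycle is found by
    log-linear interpolation between the bracketing cycles, matching how
    instruments report fractional Cq on an exponential signal.
    """
    if threshold is None:
        threshold = cfg.threshold_fraction * cfg.capacity
    f = scale * drift * np.asarray(trajectory, dtype=float)
    above = np.nonzero(f >= threshold)[0]
    if above.size == 0:
        return None
    c = int(above[0])
    if c == 0:
        return 0.0
    if f[c - 1] <= 0:
        return float(c)
    return float(c - 1 + (math.log(threshold) - math.log(f[c - 1])) / (math.log(f[c]) - math.log(f[c - 1])))


def _run_params(cfg: SimConfig, seed: int, plate_id: str) -> tuple[float, float, float]:
    """Per-run channel drifts and detection threshold."""
    rng = np.random.default_rng(_stable_seed(seed, plate_id, "__run__"))
    drift_nt = float(np.exp(rng.normal(0.0, cfg.fluor_run_sd))) if cfg.fluor_run_sd else 1.0
    drift_is = float(np.exp(rng.normal(0.0, cfg.fluor_run_sd))) if cfg.fluor_run_sd else 1.0
    threshold = cfg.threshold_fraction * cfg.capacity
    if cfg.threshold_mode == "baseline_sd" and cfg.threshold_drift_sd:
        threshold *= float(np.exp(rng.normal(0.0, cfg.threshold_drift_sd)))
    return drift_nt, drift_is, threshold


def _simulate_reaction(
    genes: Sequence[str],
    nt0: Mapping[str, float],
    is0: Mapping[str, float],
    cfg: SimConfig,
    seed: int,
    plate_id: str,
    reaction_id: str,
    drift_nt: float,
    drift_is: float,
    threshold: float,
    inhibitor_mM: float = 0.0,
    preamp: bool = True,
    poisson: bool | None = None,
) -> dict[str, tuple[float | None, float | None]]:
    """One physical workflow: multiplex pre-amp, dilution, per-gene second round."""
    if poisson is None:
        poisson = cfg.poisson_input
    rng = np.random.default_rng(_stable_seed(seed, plate_id, reaction_id))
    nt_in = np.array([nt0[g] for g in genes], dtype=float)
    is_in = np.array([is0[g] for g in genes], dtype=float)
    if poisson:
        nt_in = rng.poisson(nt_in).astype(float)
        is_in = rng.poisson(is_in).astype(float)
    if preamp:
        pre = amplify_multi(np.concatenate([nt_in, is_in]), cfg.preamp_cycles, cfg, inhibitor_mM)
        carried = pre[-1] / cfg.dilution_factor
        nt_in, is_in = carried[: len(genes)], carried[len(genes):]
    out: dict[str, tuple[float | None, float | None]] = {}
    for i, gene in enumerate(genes):
        traj_nt, traj_is = amplify(nt_in[i], is_in[i], cfg.second_cycles, cfg, inhibitor_mM)
        wrng = np.random.default_rng(_stable_seed(seed, plate_id, f"{reaction_id}:{gene}"))
        nt_cq = call_cq(traj_nt, cfg, cfg.fluor_scale_nt, drift_nt, threshold)
        is_cq = call_cq(traj_is, cfg, cfg.fluor_scale_is, drift_is, threshold)
        if cfg.cq_noise_sd:
            if nt_cq is not None:
                nt_cq = max(nt_cq + float(wrng.normal(0.0, cfg.cq_noise_sd)), 0.01)
            if is_cq is not None:
                is_cq = max(is_cq + float(wrng.normal(0.0, cfg.cq_noise_sd)), 0.01)
        out[gene] = (nt_cq, is_cq)
    return out


def _esm_rows(
    esm_mixes: Iterable[StandardsMix],
    cfg: SimConfig,
    seed: int,
    plate_id: str,
    drifts: tuple[float, float, float],
    inhibitor_mM: float = 0.0,
    preamp: bool = True,
) -> list[dict]:
    drift_nt, drift_is, threshold = drifts
    rows = []
    for esm in esm_mixes:
        genes = list(esm.genes)
        cqs = _simulate_reaction(
            genes,
            {g: esm.nt_copies(g) for g in genes},
            {g: esm.is_copies(g) for g in genes},
            cfg, seed, plate_id, esm.mix_id,
            drift_nt, drift_is, threshold, inhibitor_mM, preamp,
        )
        for gene in genes:
            nt_cq, is_cq = cqs[gene]
            rows.append(
                dict(plate_id=plate_id, well_id=f"{esm.mix_id}-{gene}", sample_id=esm.mix_id,
                     role="esm", ism_id=esm.mix_id, gene=gene, nt_cq=nt_cq, is_cq=is_cq)
            )
    return rows


def _ntc_rows(genes: Sequence[str], plate_id: str) -> list[dict]:
    return [
        dict(plate_id=plate_id, well_id=f"NTC-{g}", sample_id="NTC", role="ntc",
             ism_id=None, gene=g, nt_cq=None, is_cq=None)
        for g in genes
    ]


def simulate_assay(
    sample_copies: Mapping[str, float],
    ism: StandardsMix,
    esm_mixes: Iterable[StandardsMix],
    cfg: SimConfig,
    seed: int,
    *,
    sample_id: str = "S1",
    plate_id: str = "P1",
    inhibitor_mM: float = 0.0,
    preamp: bool = True,
    include_ntc: bool = True,
) -> pd.DataFrame:
    """Simulate one sample's full two-stage assay plus calibrators and NTC.

    ``sample_copies`` maps each gene to the NT molecules entering the
    pre-amplification reaction; every gene must be covered by the ISM.
    Returns a wells table ready for :func:`cisqpcr.quantify.quantify_wells`.
    """
    genes = list(sample_copies)
    for g in genes:
        if g not in ism.entries:
            raise ConfigurationError(f"gene {g!r} absent from ISM {ism.mix_id}")
    drifts = _run_params(cfg, seed, plate_id)
    drift_nt, drift_is, threshold = drifts
    cqs = _simulate_reaction(
        genes, sample_copies, {g: ism.is_copies(g) for g in genes},
        cfg, seed, plate_id, sample_id, drift_nt, drift_is, threshold,
        inhibitor_mM, preamp,
    )
    rows = [
        dict(plate_id=plate_id, well_id=f"{sample_id}-{g}", sample_id=sample_id, role="sample",
             ism_id=ism.mix_id, gene=g, nt_cq=cqs[g][0], is_cq=cqs[g][1])
        for g in genes
    ]
    rows += _esm_rows(esm_mixes, cfg, seed, plate_id, drifts, inhibitor_mM, preamp)
    if include_ntc:
        rows += _ntc_rows(genes, plate_id)
    return pd.DataFrame(rows, columns=WELL_COLUMNS)


def simulate_dilution_series(
    cfg: SimConfig,
    seed: int,
    *,
    gene: str = "E2F1",
    levels_molar: Sequence[float] = tuple(10.0 ** -e for e in range(11, 18)),
    replicates: int = 3,
    volume_ul: float = 1.0,
    poisson_below: float | None = None,
    calibrator_molar: Sequence[float] = DEFAULT_ESM_LEVELS,
    plate_id: str = "SERIES",
) -> tuple[pd.DataFrame, dict[str, StandardsMix], pd.Series]:
    """Simulate a 1:1 NT/IS serial dilution of the external standard.

    Each molar level becomes a pseudo-sample with NT input equal to the known
    IS input (the 1:1 mixture), measured in ``replicates`` reactions on one
    plate alongside the two ESM calibrator levels.  ``poisson_below`` turns on
    Poisson input draws for levels whose expected copies fall below the given
    count, capturing molecular sampling noise at limiting dilution.

    Returns (wells table, level mixture catalog, expected copies per sample).
    """
    drifts = _run_params(cfg, seed, plate_id)
    drift_nt, drift_is, threshold = drifts
    catalog: dict[str, StandardsMix] = {}
    expected: dict[str, float] = {}
    rows: list[dict] = []
    for i, molar in enumerate(levels_molar):
        mix_id = f"LVL{i}"
        mix = make_ism(mix_id, ref_molar=molar, target_molar=molar,
                       reference=gene, targets=(), volume_ul=volume_ul)
        catalog[mix_id] = mix
        copies = molar_to_copies(molar, volume_ul)
        poisson = poisson_below is not None and copies < poisson_below
        for r in range(replicates):
            sample_id = f"L{i}-r{r + 1}"
            expected[sample_id] = copies
            cqs = _simulate_reaction(
                [gene], {gene: copies}, {gene: copies},
                cfg, seed, plate_id, sample_id, drift_nt, drift_is, threshold,
                poisson=poisson,
            )
            nt_cq, is_cq = cqs[gene]
            rows.append(
                dict(plate_id=plate_id, well_id=sample_id, sample_id=sample_id, role="sample",
                     ism_id=mix_id, gene=gene, nt_cq=nt_cq, is_cq=is_cq)
            )
    esm_mixes = [make_esm(f"ESM-{abs(round(math.log10(c)))}", c, genes=(gene,)) for c in calibrator_molar]
    rows += _esm_rows(esm_mixes, cfg, seed, plate_id, drifts)
    rows += _ntc_rows([gene], plate_id)
    wells = pd.DataFrame(rows, columns=WELL_COLUMNS)
    return wells, catalog, pd.Series(expected, name="expected_copies")


def _lognormal(rng: np.random.Generator, median: float, gsd: float) -> float:
    if gsd <= 1.0:
        return median
    return float(median * np.exp(rng.normal(0.0, np.log(gsd))))


def simulate_cohort(
    spec: CohortSpec,
    catalog: Mapping[str, StandardsMix] | None,
    esm_mixes: Iterable[StandardsMix] | None,
    cfg: SimConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an FFPE-like benign/malignant cohort and its simulated wells.

    Per sample, relative expression of each target (per 1e6 reference
    molecules) is drawn from the class lognormal, converted to absolute input
    copies through the sample's reference-gene level, and assayed in
    ``spec.replicates`` runs (one plate per replicate batch, each with its own
    calibrators, drift and threshold).

    Returns ``(truth, wells)``: ground-truth expression per sample and the
    concatenated wells table.
    """
    catalog = dict(catalog) if catalog is not None else default_catalog()
    esm_mixes = list(esm_mixes) if esm_mixes is not None else default_esm_mixes()
    if spec.ism_id not in catalog:
        raise ConfigurationError(f"ISM {spec.ism_id!r} not in catalog")
    ism = catalog[spec.ism_id]
    rng = np.random.default_rng(_stable_seed(seed, "cohort"))
    truth_rows: list[dict] = []
    samples: list[tuple[str, str, dict[str, float]]] = []
    for label, n, medians in (
        ("benign", spec.n_benign, spec.benign_medians),
        ("malignant", spec.n_malignant, spec.malignant_medians),
    ):
        prefix = "SB" if label == "benign" else "SM"
        for i in range(n):
            sid = f"{prefix}{i + 1}"
            actb = _lognormal(rng, spec.actb_median, spec.actb_gsd)
            per_million = {g: _lognormal(rng, medians[g], spec.gsd) for g in medians}
            copies = {DEFAULT_REFERENCE: actb}
            copies.update({g: v / 1e6 * actb for g, v in per_million.items()})
            samples.append((sid, label, copies))
            row = {"sample_id": sid, "class_label": label, "ACTB_copies": actb}
            row.update(per_million)
            truth_rows.append(row)
    well_frames: list[pd.DataFrame] = []
    for r in range(spec.replicates):
        plate = f"r{r + 1}"
        drifts = _run_params(cfg, seed, plate)
        drift_nt, drift_is, threshold = drifts
        rows: list[dict] = []
        for sid, _, copies in samples:
            genes = list(copies)
            cqs = _simulate_reaction(
                genes, copies, {g: ism.is_copies(g) for g in genes},
                cfg, seed, plate, sid, drift_nt, drift_is, threshold,
            )
            rows += [
                dict(plate_id=plate, well_id=f"{sid}-{g}", sample_id=sid, role="sample",
                     ism_id=ism.mix_id, gene=g, nt_cq=cqs[g][0], is_cq=cqs[g][1])
                for g in genes
            ]
        rows += _esm_rows(esm_mixes, cfg, seed, plate, drifts)
        rows += _ntc_rows(list(DEFAULT_GENES), plate)
        well_frames.append(pd.DataFrame(rows, columns=WELL_COLUMNS))
    truth = pd.DataFrame(truth_rows)
    wells = pd.concat(well_frames, ignore_index=True) if well_frames else pd.DataFrame(columns=WELL_COLUMNS)
    return truth, wells
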