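"""Internal and external standards mixtures.

Competitive qPCR measures each native template (NT) against a known number of
co-amplified synthetic internal-standard (IS) molecules.  The IS for every
assay gene are pre-combined into an internal standards mixture (ISM) so that
one pipetting step fixes the IS copy number of all genes at once.  An external
standards mixture (ESM) is a 1:1 NT/IS mixture of every gene, run alongside
the samples to calibrate channel-intensity and threshold drift: its expected
Cq difference is zero, so any measured deviation is an instrument offset.

Copy numbers are derived from molar concentrations with a fixed Avogadro
constant; rounding to one or two significant figures is a presentation option
only and never feeds back into downstream arithmetic.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import ConfigurationError, InvalidInputError

#: Avogadro constant (1/mol), fixed for reproducible copy-number conversion.
AVOGADRO = 6.02214e23

#: Default gene panel: three targets plus the loading-control reference.
DEFAULT_GENES = ("ACTB", "MYC", "E2F1", "CDKN1A")
DEFAULT_REFERENCE = "ACTB"
DEFAULT_TARGETS = ("MYC", "E2F1", "CDKN1A")


def round_sig(x: float, sig: int) -> float:
    """Round ``x`` to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    digits = sig - 1 - math.floor(math.log10(abs(x)))
    return round(x, digits)


def molar_to_copies(molar: float, volume_ul: float, rounding: str = "none") -> float:
    """Convert a molar concentration and reaction volume to molecules per reaction.

    Parameters
    ----------
    molar : concentration in mol/L (must be >= 0).
    volume_ul : volume added to the reaction, in microlitres (> 0).
    rounding : ``"none"`` for full precision, ``"sig_figs_1"`` to round to one
        significant figure (the convention used when quoting nominal mixture
        copy numbers, e.g. 1e-12 M in 1 ul -> 600000).
    """
    if molar < 0:
        raise InvalidInputError(f"negative molar concentration: {molar}")
    if volume_ul <= 0:
        raise InvalidInputError(f"non-positive volume: {volume_ul} ul")
    copies = molar * (volume_ul * 1e-6) * AVOGADRO
    if rounding == "sig_figs_1":
        return round_sig(copies, 1)
    if rounding != "none":
        raise InvalidInputError(f"unknown rounding mode: {rounding!r}")
    return copies


@dataclass(frozen=True)
class MixEntry:
    """Per-gene composition of a standards mixture.

    ``nt_molar`` is present only for ESM entries (a 1:1 NT/IS mixture); ISM
    entries carry internal standard alone.
    """

    is_molar: float
    volume_ul: float = 1.0
    nt_molar: float | None = None

    def __post_init__(self) -> None:
        if self.is_molar < 0:
            raise InvalidInputError("is_molar must be >= 0")
        if self.volume_ul <= 0:
            raise InvalidInputError("volume_ul must be > 0")


@dataclass(frozen=True)
class StandardsMix:
    """A named ISM or ESM: gene -> :class:`MixEntry`."""

    mix_id: str
    kind: str  # "ISM" or "ESM"
    entries: Mapping[str, MixEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("ISM", "ESM"):
            raise ConfigurationError(f"kind must be ISM or ESM, got {self.kind!r}")
        for gene, entry in self.entries.items():
            if self.kind == "ISM" and entry.nt_molar is not None:
                raise ConfigurationError(
                    f"{self.mix_id}: ISM entry for {gene} must not carry an NT component"
                )
            if self.kind == "ESM":
                if entry.nt_molar is None or entry.nt_molar != entry.is_molar:
                    raise ConfigurationError(
                        f"{self.mix_id}: ESM entry for {gene} must be a 1:1 NT/IS mixture"
                    )

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def is_copies(self, gene: str, rounding: str = "none") -> float:
        """Internal-standard molecules per reaction for ``gene``."""
        entry = self._entry(gene)
        return molar_to_copies(entry.is_molar, entry.volume_ul, rounding)

    def nt_copies(self, gene: str, rounding: str = "none") -> float:
        """Native-template molecules per reaction (ESM only)."""
        entry = self._entry(gene)
        if entry.nt_molar is None:
            raise ConfigurationError(f"{self.mix_id} has no NT component for {gene}")
        return molar_to_copies(entry.nt_molar, entry.volume_ul, rounding)

    def _entry(self, gene: str) -> MixEntry:
        try:
            return self.entries[gene]
        except KeyError:
            raise ConfigurationError(f"gene {gene!r} absent from mixture {self.mix_id}") from None


@dataclass(frozen=True)
class IsmChoice:
    """Result of matching an expected abundance to the ISM catalog."""

    mix_id: str
    is_copies: float
    log10_ratio: float
    within_gate: bool


def select_ism(
    expected_copies: float,
    gene: str,
    catalog: Iterable[StandardsMix],
    fold_limit: float = 10.0,
) -> IsmChoice:
    """Pick the catalog ISM whose IS copy number best matches an expected abundance.

    The match is closest-on-a-log-scale; ties keep the first catalog entry in
    declared order.  ``within_gate`` is False when even the best entry leaves
    the NT:IS ratio outside ``[1/fold_limit, fold_limit]`` (the analysable
    window), signalling that a dedicated dilution or a new mixture is needed.
    """
    catalog = [m for m in catalog if m.kind == "ISM" and gene in m.entries]
    if not catalog:
        raise ConfigurationError(f"no ISM in catalog carries gene {gene!r}")
    if expected_copies <= 0:
        raise InvalidInputError("expected_copies must be > 0 to select an ISM")
    best: IsmChoice | None = None
    for mix in catalog:
        copies = mix.is_copies(gene)
        if copies <= 0:
            continue
        log_ratio = math.log10(expected_copies / copies)
        if best is None or abs(log_ratio) < abs(best.log10_ratio) - 1e-12:
            best = IsmChoice(
                mix_id=mix.mix_id,
                is_copies=copies,
                log10_ratio=log_ratio,
                within_gate=abs(log_ratio) <= math.log10(fold_limit) + 1e-12,
            )
    if best is None:
        raise ConfigurationError(f"no ISM in catalog has positive IS copies for {gene!r}")
    return best


def make_ism(mix_id: str, ref_molar: float, target_molar: float,
             reference: str = DEFAULT_REFERENCE, targets: Iterable[str] = DEFAULT_TARGETS,
             volume_ul: float = 1.0) -> StandardsMix:
    """Build an ISM with one concentration for the reference and one for all targets."""
    entries = {reference: MixEntry(is_molar=ref_molar, volume_ul=volume_ul)}
    for gene in targets:
        entries[gene] = MixEntry(is_molar=target_molar, volume_ul=volume_ul)
    return StandardsMix(mix_id=mix_id, kind="ISM", entries=entries)


def make_esm(mix_id: str, molar: float, genes: Iterable[str] = DEFAULT_GENES,
             volume_ul: float = 1.0) -> StandardsMix:
    """Build a 1:1 NT/IS external standards mixture at a single concentration."""
    entries = {g: MixEntry(is_molar=molar, nt_molar=molar, volume_ul=volume_ul) for g in genes}
    return StandardsMix(mix_id=mix_id, kind="ESM", entries=entries)


def default_catalog() -> dict[str, StandardsMix]:
    """Illustrative ISM catalog A-F spanning the assay's working range.

    D and E follow the published compositions (reference IS 1e-12 M with
    targets at 1e-14 and 1e-15 M respectively, i.e. ~600000 reference /
    6000 or 600 target molecules per 1 ul); the remaining letters fill out
    a plausible range and are expected to be overridden from run config for
    any real mixture lot.
    """
    spec = {
        "ISM-A": (1e-11, 1e-13),
        "ISM-B": (1e-12, 1e-13),
        "ISM-C": (1e-13, 1e-15),
        "ISM-D": (1e-12, 1e-14),
        "ISM-E": (1e-12, 1e-15),
        "ISM-F": (1e-13, 1e-16),
    }
    return {mid: make_ism(mid, ref, tgt) for mid, (ref, tgt) in spec.items()}


#: Working ESM concentrations measured in every run (mol/L).
DEFAULT_ESM_LEVELS = (1e-13, 1e-14)


def default_esm_mixes() -> list[StandardsMix]:
    """The two working ESM dilutions run as calibrators in each experiment."""
    return [make_esm(f"ESM-{abs(round(math.log10(c)))}", c) for c in DEFAULT_ESM_LEVELS]
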