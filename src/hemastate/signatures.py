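"""Mutational signature refitting on 96-channel substitution counts.

Counts over the 96 trinucleotide substitution channels are fit as a
non-negative combination of catalog signatures by multinomial maximum
likelihood (multiplicative updates; equivalent to minimizing KL
divergence to the observed spectrum). Fitting is two-stage: all catalog
signatures are fitted first, then signatures contributing less than a
retention fraction (default 2%) are dropped and the retained set refit.
For low mutation counts (< 100 by default), biologically implausible
C>T signatures (ultraviolet SBS7a, mismatch-repair SBS6 by default) are
removed and the fit re-run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._optim import fit_fixed_basis_poisson
from .synthetic import SBS96_CHANNELS

__all__ = ["SignatureExposure", "load_catalog", "validate_catalog",
           "fit_signature_exposures", "prune_implausible",
           "DEFAULT_BLOCKLIST"]

DEFAULT_BLOCKLIST = ("SBS7a", "SBS6")

_FLOOR = 1e-9  # probability floor so restricted catalogs keep full support


def validate_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    """Check a channels x signatures catalog: 96 rows, columns on the
    probability simplex (renormalized within 1e-6 tolerance)."""
    if catalog.shape[0] != 96:
        raise ValueError("catalog must have exactly 96 channels")
    mat = catalog.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("catalog entries must be non-negative")
    sums = mat.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("each signature column must sum to 1")
    return catalog / sums


def load_catalog(path: str) -> pd.DataFrame:
    """Read a COSMIC-style CSV (channel labels in the first column)."""
    df = pd.read_csv(path, index_col=0)
    df = df.reindex(SBS96_CHANNELS)
    if df.isna().any().any():
        raise ValueError("catalog is missing trinucleotide channels")
    return validate_catalog(df)


@dataclass
class SignatureExposure:
    """Fitted signature contributions for one mutation spectrum."""

    counts: pd.Series            # fitted mutation counts per signature
    fractions: pd.Series         # fractions over the final retained set
    retained: list
    dropped_low: list = field(default_factory=list)
    dropped_implausible: list = field(default_factory=list)
    loglik: float = float("nan")
    total: float = 0.0

    def __post_init__(self) -> None:
        if (self.counts < 0).any():
            raise ValueError("fitted counts must be non-negative")
        if len(self.retained) and not np.isclose(self.fractions.sum(), 1.0,
                                                 atol=1e-9):
            raise ValueError("fractions over the retained set must sum to 1")

    def reconstruction(self, catalog: pd.DataFrame) -> np.ndarray:
        frac = self.counts / max(self.counts.sum(), 1e-300)
        return catalog[self.counts.index].to_numpy() @ frac.to_numpy()


def _fit(counts96: np.ndarray, catalog: pd.DataFrame):
    basis = catalog.to_numpy(dtype=float) + _FLOOR
    basis = basis / basis.sum(axis=0)
    fit = fit_fixed_basis_poisson(counts96, basis)
    total = counts96.sum()
    return pd.Series(fit.fractions * total, index=catalog.columns), fit.loglik


def fit_signature_exposures(counts96, catalog: pd.DataFrame,
                            retain_frac: float = 0.02) -> SignatureExposure:
    """Two-stage non-negative signature fit with a retention threshold.

    Stage 1 fits all catalog signatures by multinomial ML; signatures
    contributing less than ``retain_frac`` of mutations are dropped and
    the retained set refit (stage 2). Deterministic.
    """
    counts96 = np.asarray(counts96, dtype=float)
    if counts96.shape != (96,):
        raise ValueError("counts must be a 96-channel vector")
    if counts96.sum() <= 0:
        raise ValueError("zero total mutation count; nothing to fit")
    catalog = validate_catalog(catalog)
    stage1, _ll1 = _fit(counts96, catalog)
    frac1 = stage1 / stage1.sum()
    retained = list(frac1.index[frac1 >= retain_frac])
    dropped = list(frac1.index[frac1 < retain_frac])
    if not retained:  # degenerate: keep the single largest contributor
        retained = [frac1.idxmax()]
        dropped = [s for s in frac1.index if s != retained[0]]
    stage2, ll2 = _fit(counts96, catalog[retained])
    counts = stage2.reindex(catalog.columns, fill_value=0.0)
    fractions = stage2 / stage2.sum()
    return SignatureExposure(counts=counts, fractions=fractions,
                             retained=retained, dropped_low=dropped,
                             loglik=ll2, total=float(counts96.sum()))


def prune_implausible(exposure: SignatureExposure, counts96,
                      catalog: pd.DataFrame,
                      blocklist=DEFAULT_BLOCKLIST,
                      low_count: int = 100) -> SignatureExposure:
    """Remove blocklisted signatures from low-count fits and refit.

    Applies only when the spectrum's total mutation count is below
    ``low_count``; larger spectra are returned unchanged, as are fits
    with no blocklisted signature retained.
    """
    counts96 = np.asarray(counts96, dtype=float)
    total = counts96.sum()
    hit = [s for s in exposure.retained if s in set(blocklist)]
    if total >= low_count or not hit:
        return exposure
    keep = [s for s in exposure.retained if s not in set(blocklist)]
    if not keep:
        raise ValueError("pruning would remove every retained signature")
    stage, ll = _fit(counts96, validate_catalog(catalog)[keep])
    counts = stage.reindex(catalog.columns, fill_value=0.0)
    return SignatureExposure(counts=counts, fractions=stage / stage.sum(),
                             retained=keep,
                             dropped_low=exposure.dropped_low,
                             dropped_implausible=hit, loglik=ll, total=total)
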