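"""Checker-based polynomial color correction.

A 24-patch color checker photographed by the capture device provides paired
(observed, reference) RGB triplets.  A polynomial regression from observed to
reference colors — one coefficient column per output channel — maps raw
device RGB into standard sRGB.  Degree 2 with the ten monomials
{1, R, G, B, R^2, G^2, B^2, RG, RB, GB} is the default: it is well
conditioned with 24 patches while capturing channel cross-talk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from itertools import combinations_with_replacement
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import FittingError, InputValidationError
from .types import FacialImage

N_PATCHES = 24


@dataclass
class PatchSet:
    """24 RGB triplets in [0, 1], either observed (device) or reference."""

    colors: np.ndarray
    role: str  # "observed" | "reference"

    def __post_init__(self):
        self.colors = np.asarray(self.colors, dtype=float)
        if self.colors.shape != (N_PATCHES, 3):
            raise InputValidationError(
                f"a patch set holds exactly {N_PATCHES}x3 colors, "
                f"got {self.colors.shape}"
            )
        if self.colors.min() < 0 or self.colors.max() > 1:
            raise InputValidationError("patch colors must lie in [0, 1]")
        if self.role not in ("observed", "reference"):
            raise InputValidationError(f"unknown patch role {self.role!r}")


@dataclass
class CorrectionModel:
    """Fitted polynomial map from device RGB to sRGB."""

    degree: int
    terms: list[tuple[int, int, int]]  # monomial exponents over (R, G, B)
    coefficients: np.ndarray  # (n_terms, 3)


def monomial_terms(degree: int) -> list[tuple[int, int, int]]:
    """Exponent triples of all monomials in (R, G, B) up to total degree."""
    terms: list[tuple[int, int, int]] = []
    for d in range(degree + 1):
        for combo in combinations_with_replacement(range(3), d):
            e = [0, 0, 0]
            for c in combo:
                e[c] += 1
            terms.append(tuple(e))
    return terms


def _design_matrix(colors: np.ndarray, terms) -> np.ndarray:
    cols = [
        colors[:, 0] ** er * colors[:, 1] ** eg * colors[:, 2] ** eb
        for (er, eg, eb) in terms
    ]
    return np.column_stack(cols)


class PolynomialColorCorrector(TransformerMixin, BaseEstimator):
    """Least-squares polynomial RGB-to-sRGB corrector.

    Parameters
    ----------
    degree : int
        Polynomial total degree, one of {1, 2, 3}.  The monomial count must
        not exceed the 24 available patches (degree 3 gives 20 terms).

    Attributes
    ----------
    terms_ : list of exponent triples
    coefficients_ : ndarray (n_terms, 3)
        One column per output channel.
    residual_rmse_ : float
        Root-mean-square residual of the fit over the 24 patches.
    """

    def __init__(self, degree: int = 2):
        self.degree = degree

    def fit(self, X, y):
        """Fit the map from observed patch colors ``X`` to reference ``y``."""
        if self.degree not in (1, 2, 3):
            raise InputValidationError("degree must be 1, 2, or 3")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.shape != y.shape or X.ndim != 2 or X.shape[1] != 3:
            raise InputValidationError(
                f"observed and reference patch arrays must both be (N, 3); "
                f"got {X.shape} and {y.shape}"
            )
        terms = monomial_terms(self.degree)
        if len(terms) > X.shape[0]:
            raise InputValidationError(
                f"{len(terms)} monomials exceed the {X.shape[0]} patches"
            )
        design = _design_matrix(X, terms)
        coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        if rank < len(terms):
            raise FittingError(
                f"design matrix rank-deficient: {len(terms) - rank} of "
                f"{len(terms)} terms unresolvable"
            )
        self.terms_ = terms
        self.coefficients_ = coef
        self.residual_rmse_ = float(
            np.sqrt(np.mean((design @ coef - y) ** 2))
        )
        return self

    def transform(self, X):
        """Map an (N, 3) array of RGB colors through the fitted polynomial."""
        check_is_fitted(self, "coefficients_")
        X = np.asarray(X, dtype=float)
        return _design_matrix(X, self.terms_) @ self.coefficients_

    def to_model(self) -> CorrectionModel:
        check_is_fitted(self, "coefficients_")
        return CorrectionModel(self.degree, list(self.terms_), self.coefficients_)


def fit_correction_model(
    observed: PatchSet, reference: PatchSet, degree: int = 2
) -> CorrectionModel:
    """Train the polynomial corrector on paired checker patch sets."""
    if observed.role != "observed":
        raise InputValidationError("first patch set must have role 'observed'")
    if reference.role != "reference":
        raise InputValidationError("second patch set must have role 'reference'")
    est = PolynomialColorCorrector(degree=degree)
    est.fit(observed.colors, reference.colors)
    return est.to_model()


def apply_correction(image: FacialImage, model: CorrectionModel) -> FacialImage:
    """Map every pixel through the polynomial and clip to [0, 1].

    The input must be tagged ``raw``; the output is tagged ``srgb`` so a
    second application (double correction) is rejected.
    """
    if image.space_tag != "raw":
        raise InputValidationError(
            "image is already corrected (space_tag != 'raw')"
        )
    flat = image.pixels.reshape(-1, 3)
    mapped = _design_matrix(flat, model.terms) @ model.coefficients
    mapped = np.clip(mapped, 0.0, 1.0)
    return FacialImage(mapped.reshape(image.pixels.shape), space_tag="srgb")


# ---------------------------------------------------------------------------
# persistence and shipped reference table
# ---------------------------------------------------------------------------

def save_model(model: CorrectionModel, path: str | Path) -> None:
    payload = {
        "degree": model.degree,
        "terms": [list(t) for t in model.terms],
        "coefficients": model.coefficients.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> CorrectionModel:
    payload = json.loads(Path(path).read_text())
    return CorrectionModel(
        degree=int(payload["degree"]),
        terms=[tuple(t) for t in payload["terms"]],
        coefficients=np.asarray(payload["coefficients"], dtype=float),
    )


def load_patch_csv(path: str | Path, role: str) -> PatchSet:
    """Read a patch table CSV (columns patch_id, R, G, B; 8-bit auto-scaled)."""
    df = pd.read_csv(path)
    cols = df[["R", "G", "B"]].to_numpy(dtype=float)
    if cols.max() > 1.0:  # 8-bit integer convention
        cols = cols / 255.0
    return PatchSet(cols, role)


def reference_checker(role: str = "reference") -> PatchSet:
    """The shipped 24-patch checker reference values (sRGB, D65)."""
    with resources.files("nbds").joinpath("data/colorchecker_srgb.csv").open() as fh:
        df = pd.read_csv(fh)
    cols = df[["R", "G", "B"]].to_numpy(dtype=float) / 255.0
    return PatchSet(cols, role)
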