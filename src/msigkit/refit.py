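"""Signature refitting by non-negative least squares (NNLS).

Given a catalog of observed mutation counts and a fixed set of reference
signatures (per-channel probability vectors, e.g. COSMIC SBS96), refitting
estimates for each sample the nonnegative *exposures* x minimizing

    || S x - m ||^2,    x >= 0,

where S is the channels × signatures profile matrix and m the sample's count
vector.  The per-sample *r-norm* is the attained minimum — the sum of squared
residuals of the decomposition.  The solver is the Lawson–Hanson active-set
algorithm, implemented here: starting from x = 0, the signature with the most
positive dual (gradient) component enters the passive set, an unconstrained
least-squares problem is solved on that set, and any coefficients driven
negative are stepped back to the boundary and dropped; at termination the
Karush–Kuhn–Tucker conditions hold, so the solution is the exact constrained
minimizer.

By default refitting is performed on raw counts, so exposures are in
mutation-count units and the r-norm is on the count scale; pass
``normalize_input=True`` to refit normalized spectra instead (exposures then
sum to ≈1).  Relative exposures (fractions of a sample's total activity) are
derived afterwards either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import MutationalCatalog, to_spectrum
from .channels import ChannelSchema
from .errors import (
    ConvergenceError,
    SampleLookupError,
    SchemaMismatchError,
    ValidationError,
)


@dataclass
class SignatureSet:
    """Reference signatures: channels × signatures matrix of probabilities.

    Each column is a probability vector over the schema's channels (sums to 1
    within 1e-6, all entries nonnegative).
    """

    schema: ChannelSchema
    signature_ids: list[str]
    profiles: np.ndarray
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signature_ids = [str(s) for s in self.signature_ids]
        if len(set(self.signature_ids)) != len(self.signature_ids):
            raise ValidationError("duplicate signature ids")
        p = np.asarray(self.profiles, dtype=float)
        if p.ndim != 2 or p.shape != (len(self.schema), len(self.signature_ids)):
            raise ValidationError(
                f"profiles shape {p.shape} does not match "
                f"{len(self.schema)} channels × {len(self.signature_ids)} signatures"
            )
        if p.size and p.min() < 0:
            raise ValidationError("signature profiles must be nonnegative")
        sums = p.sum(axis=0)
        bad = np.where(np.abs(sums - 1.0) > 1e-6)[0]
        if bad.size:
            raise ValidationError(
                f"signature column {self.signature_ids[bad[0]]!r} sums to "
                f"{sums[bad[0]]:.8f}, expected 1"
            )
        self.profiles = p

    @property
    def n_signatures(self) -> int:
        return len(self.signature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.profiles, index=list(self.schema.channels), columns=self.signature_ids
        )


def read_signatures_csv(path, schema: ChannelSchema) -> SignatureSet:
    """Read a signature matrix (header ``mutationType,<sig1>,...``) from CSV.

    Rows are reordered into schema channel order; every schema channel must
    be present exactly once.
    """
    frame = pd.read_csv(path)
    if frame.columns[0] != "mutationType":
        raise ValidationError(f"{path}: first column must be 'mutationType'")
    labels = frame["mutationType"].astype(str).tolist()
    for label in labels:
        if label not in schema:
            raise SchemaMismatchError(
                f"{path}: unknown channel label {label!r} for schema {schema.name}"
            )
    if sorted(labels) != sorted(schema.channels):
        missing = sorted(set(schema.channels) - set(labels))
        raise SchemaMismatchError(f"{path}: missing channels {missing[:5]}...")
    order = [labels.index(c) for c in schema.channels]
    sig_ids = [str(c) for c in frame.columns[1:]]
    profiles = frame.iloc[order, 1:].to_numpy(dtype=float)
    return SignatureSet(schema, sig_ids, profiles)


def write_signatures_csv(signatures: SignatureSet, path) -> None:
    signatures.to_frame().reset_index(names="mutationType").to_csv(
        path, index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# The solver


def nnls_solve(
    design: np.ndarray,
    target: np.ndarray,
    max_iter: int | None = None,
) -> tuple[np.ndarray, float]:
    """Solve min ||design·x − target||² subject to x ≥ 0 (Lawson–Hanson).

    Returns ``(coefficients, rnorm)`` where ``rnorm`` is the minimum *squared*
    residual norm (sum of squared residuals).  The design must have at least
    one column and no all-zero column.

    Raises
    ------
    ValidationError
        On non-finite input, dimension mismatch, or an all-zero column.
    ConvergenceError
        If the active-set loop exceeds its iteration budget (3·k outer
        iterations by default) — does not occur on well-posed problems.
    """
    A = np.asarray(design, dtype=float)
    b = np.asarray(target, dtype=float)
    if A.ndim != 2 or A.shape[1] < 1:
        raise ValidationError("design must be 2-D with at least one column")
    if b.ndim != 1 or b.shape[0] != A.shape[0]:
        raise ValidationError(
            f"target length {b.shape} does not match design rows {A.shape[0]}"
        )
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(b))):
        raise ValidationError("non-finite values in design or target")
    zero_cols = np.where(~A.any(axis=0))[0]
    if zero_cols.size:
        raise ValidationError(f"design column {zero_cols[0]} is all zero")

    m, k = A.shape
    if max_iter is None:
        max_iter = max(3 * k, 10)

    x = np.zeros(k)
    passive = np.zeros(k, dtype=bool)
    w = A.T @ b  # dual vector A'(b - Ax) at x = 0
    # dual-feasibility tolerance on the scale of the initial gradient
    tol = 10.0 * np.finfo(float).eps * max(np.abs(w).max(initial=0.0), 1.0)

    outer = 0
    while (~passive).any() and np.max(w[~passive], initial=-np.inf) > tol:
        outer += 1
        if outer > max_iter:
            raise ConvergenceError(
                f"NNLS active-set loop did not converge in {max_iter} iterations"
            )
        # entering variable: largest dual among the zero set, lowest index on ties
        free = np.where(~passive)[0]
        j = free[np.argmax(w[free])]
        passive[j] = True

        # inner loop: restore feasibility of the passive-set LS solution
        while True:
            idx = np.where(passive)[0]
            z, *_ = np.linalg.lstsq(A[:, idx], b, rcond=None)
            if np.all(z > 0):
                x = np.zeros(k)
                x[idx] = z
                break
            # step toward z until the first passive coefficient hits zero
            mask = z <= 0
            alpha = np.min(x[idx][mask] / (x[idx][mask] - z[mask]))
            x[idx] = x[idx] + alpha * (z - x[idx])
            drop = idx[x[idx] <= tol]
            x[drop] = 0.0
            passive[drop] = False
            if not passive.any():
                x = np.zeros(k)
                break
        if not passive.any():
            break
        w = A.T @ (b - A @ x)

    residual = b - A @ x
    return x, float(residual @ residual)


# ---------------------------------------------------------------------------
# Model / results


@dataclass
class ExposureResult:
    """Refitting results: nonnegative exposures and per-sample r-norms.

    ``exposures`` is samples × signatures (mutation-count units unless the
    model refit normalized spectra); ``rnorm[i]`` is the sum of squared
    residuals of sample i's reconstruction.
    """

    sample_ids: list[str]
    signature_ids: list[str]
    exposures: np.ndarray
    rnorm: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.exposures, dtype=float)
        r = np.asarray(self.rnorm, dtype=float)
        if e.shape != (len(self.sample_ids), len(self.signature_ids)):
            raise ValidationError("exposures shape mismatch")
        if r.shape != (len(self.sample_ids),):
            raise ValidationError("rnorm length mismatch")
        if e.size and e.min() < -1e-12:
            raise ValidationError("exposures must be nonnegative")
        if r.size and r.min() < -1e-12:
            raise ValidationError("rnorm must be nonnegative")
        self.exposures = np.maximum(e, 0.0)
        self.rnorm = np.maximum(r, 0.0)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, sample_id: str) -> np.ndarray:
        try:
            return self.exposures[self.sample_ids.index(sample_id)]
        except ValueError:
            raise SampleLookupError(
                f"unknown sample {sample_id!r}; available: {self.sample_ids}"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        """Exposures + r-norm as a DataFrame (one row per sample)."""
        frame = pd.DataFrame(
            self.exposures, index=self.sample_ids, columns=self.signature_ids
        )
        frame["rnorm"] = self.rnorm
        return frame

    def write_csv(self, path) -> None:
        """Write ``sample,<sig1>,...,<sigK>,rnorm`` CSV."""
        self.to_frame().reset_index(names="sample").to_csv(
            path, index=False, lineterminator="\n"
        )

    def summary(self) -> str:
        """Human-readable overview of the fit."""
        tot = self.exposures.sum(axis=1)
        lines = [
            "Signature refitting (NNLS) results",
            f"  samples:    {self.n_samples}",
            f"  signatures: {len(self.signature_ids)} ({', '.join(self.signature_ids)})",
            f"  mean assigned activity per sample: {tot.mean():.2f}",
            f"  r-norm (sum sq. residuals): median {np.median(self.rnorm):.4g}, "
            f"max {self.rnorm.max(initial=0.0):.4g}",
            "  mean exposure per signature:",
        ]
        means = self.exposures.mean(axis=0)
        for sig, mu in sorted(zip(self.signature_ids, means), key=lambda t: -t[1]):
            lines.append(f"    {sig:<12} {mu:12.3f}")
        return "\n".join(lines)


def read_exposures_csv(path) -> ExposureResult:
    """Read an exposure CSV written by :meth:`ExposureResult.write_csv`."""
    frame = pd.read_csv(path)
    if frame.columns[0] != "sample" or frame.columns[-1] != "rnorm":
        raise ValidationError(
            f"{path}: expected header sample,<signatures...>,rnorm"
        )
    sig_ids = [str(c) for c in frame.columns[1:-1]]
    return ExposureResult(
        sample_ids=frame["sample"].astype(str).tolist(),
        signature_ids=sig_ids,
        exposures=frame[sig_ids].to_numpy(dtype=float),
        rnorm=frame["rnorm"].to_numpy(dtype=float),
    )


class SignatureRefit:
    """NNLS refitting model for a catalog against a fixed signature set.

    Parameters
    ----------
    catalog
        Observed mutation counts; its schema must match the signatures'
        schema exactly (same labels, same order).
    signatures
        Reference signature set (columns are probability vectors).
    normalize_input
        If True, refit each sample's normalized spectrum instead of its raw
        counts; exposures then sum to ≈1 per sample and the r-norm is on the
        spectrum scale.

    Examples
    --------
    >>> result = SignatureRefit(catalog, signatures).fit()
    >>> result.to_frame()          # exposures + rnorm per sample
    >>> result.summary()
    """

    def __init__(
        self,
        catalog: MutationalCatalog,
        signatures: SignatureSet,
        normalize_input: bool = False,
    ) -> None:
        if catalog.schema.channels != signatures.schema.channels:
            a, b = catalog.schema.channels, signatures.schema.channels
            for i in range(max(len(a), len(b))):
                la = a[i] if i < len(a) else "<absent>"
                lb = b[i] if i < len(b) else "<absent>"
                if la != lb:
                    raise SchemaMismatchError(
                        f"catalog/signature schema mismatch at channel {i}: "
                        f"{la!r} vs {lb!r}"
                    )
        self.catalog = catalog
        self.signatures = signatures
        self.normalize_input = normalize_input

    def fit(self) -> ExposureResult:
        """Solve one NNLS problem per sample; deterministic, no randomness."""
        S = self.signatures.profiles
        n = self.catalog.n_samples
        exposures = np.zeros((n, self.signatures.n_signatures))
        rnorm = np.zeros(n)
        for i, sample in enumerate(self.catalog.sample_ids):
            if self.normalize_input:
                target = to_spectrum(self.catalog, sample).values
            else:
                target = self.catalog.counts[i].astype(float)
            exposures[i], rnorm[i] = nnls_solve(S, target)
        return ExposureResult(
            sample_ids=list(self.catalog.sample_ids),
            signature_ids=list(self.signatures.signature_ids),
            exposures=exposures,
            rnorm=rnorm,
        )


def refit_exposures(
    catalog: MutationalCatalog,
    signatures: SignatureSet,
    normalize_input: bool = False,
) -> ExposureResult:
    """Functional shorthand for ``SignatureRefit(catalog, signatures).fit()``."""
    return SignatureRefit(catalog, signatures, normalize_input=normalize_input).fit()


def relative_exposures(result: ExposureResult, sample_id: str) -> pd.DataFrame:
    """One sample's activities and their fractions of total activity.

    Rows are sorted by fraction descending (ties broken by signature id);
    fractions sum to 1 when any activity is positive.  If all activities are
    zero the fractions are all zero and a warning is issued.
    """
    import warnings

    activities = result.row(sample_id)
    total = activities.sum()
    if total > 0:
        fractions = activities / total
    else:
        warnings.warn(f"sample {sample_id!r} has no positive activity", stacklevel=2)
        fractions = np.zeros_like(activities)
    frame = pd.DataFrame(
        {
            "signature_id": result.signature_ids,
            "activity": activities,
            "fraction": fractions,
        }
    )
    return frame.sort_values(
        ["fraction", "signature_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
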