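"""Synthetic catalogs with known ground truth.

The generator draws a set of reference-like signature profiles from a
symmetric Dirichlet over the channels (a small concentration yields the
spiky, sparse profiles characteristic of real mutational signatures), gives
each sample a small random subset of active signatures with Dirichlet(1)
relative weights, draws the sample's total mutation burden from a lognormal
(heavy right tail, mimicking the orders-of-magnitude spread of per-sample
mutation counts across cancer types), and finally adds counting noise:
independent Poisson counts per channel, a multinomial draw of fixed total,
or none (rounded expectations).

Randomness comes from a single seed; per-component and per-sample substreams
are derived from fixed offsets, so generating more samples never reshuffles
the earlier ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .catalog import MutationalCatalog
from .channels import SBS96, ChannelSchema, get_schema
from .errors import ValidationError
from .refit import ExposureResult, SignatureSet

_NOISE_MODES = ("poisson", "multinomial", "none")

# fixed substream offsets (see module docstring)
_STREAM_SIGNATURES = 0
_STREAM_SAMPLES = 1


@dataclass
class SimulationSpec:
    """Parameters of one synthetic-catalog draw.

    Attributes
    ----------
    n_samples, n_signatures
        Catalog dimensions.
    schema
        Channel schema (default SBS96).
    signature_concentration
        Symmetric Dirichlet concentration for signature profiles; small
        values (≪1) give sparse, signature-like columns.
    exposures_active_per_sample
        How many signatures contribute to each sample.
    burden_mean, burden_dispersion
        Mean and coefficient of variation of the lognormal per-sample total
        mutation count.
    noise
        ``"poisson"`` (per-channel), ``"multinomial"`` (fixed total) or
        ``"none"`` (rounded expected counts).
    seed
        Root seed for all randomness.
    """

    n_samples: int = 50
    n_signatures: int = 5
    schema: ChannelSchema = field(default_factory=lambda: SBS96)
    signature_concentration: float = 0.1
    exposures_active_per_sample: int = 3
    burden_mean: float = 5000.0
    burden_dispersion: float = 1.0
    noise: str = "poisson"
    seed: int = 20240119

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_signatures < 1:
            raise ValidationError("n_samples and n_signatures must be ≥ 1")
        if not 1 <= self.exposures_active_per_sample <= self.n_signatures:
            raise ValidationError(
                "exposures_active_per_sample must be in [1, n_signatures]"
            )
        if self.burden_mean <= 0 or self.burden_dispersion <= 0:
            raise ValidationError("burden_mean and burden_dispersion must be > 0")
        if self.signature_concentration <= 0:
            raise ValidationError("signature_concentration must be > 0")
        if self.noise not in _NOISE_MODES:
            raise ValidationError(f"noise must be one of {_NOISE_MODES}")

    @classmethod
    def from_json(cls, path) -> "SimulationSpec":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        if "schema" in data:
            data["schema"] = get_schema(data["schema"])
        return cls(**data)

    def to_json(self, path) -> None:
        data = {k: v for k, v in asdict(self).items() if k != "schema"}
        data["schema"] = self.schema.name
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(data, fh, indent=2)
            fh.write("\n")


def _signature_rng(spec: SimulationSpec) -> np.random.Generator:
    return np.random.default_rng([spec.seed, _STREAM_SIGNATURES])


def _sample_rng(spec: SimulationSpec, i: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, _STREAM_SAMPLES, i])


def generate_signatures(spec: SimulationSpec) -> SignatureSet:
    """Draw ``n_signatures`` Dirichlet profile columns over the schema."""
    rng = _signature_rng(spec)
    n_ch = len(spec.schema)
    profiles = rng.dirichlet(
        np.full(n_ch, spec.signature_concentration), size=spec.n_signatures
    ).T  # channels × signatures
    # renormalize away accumulated rounding so column sums are exactly 1
    profiles = profiles / profiles.sum(axis=0, keepdims=True)
    ids = [f"SIM{k + 1}" for k in range(spec.n_signatures)]
    return SignatureSet(spec.schema, ids, profiles,
                        metadata={"source": "synthetic", "seed": str(spec.seed)})


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and coefficient of variation."""
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def generate_catalog(
    spec: SimulationSpec,
) -> tuple[MutationalCatalog, ExposureResult, SignatureSet]:
    """Simulate a catalog; returns (catalog, true exposures, signatures).

    The returned ``ExposureResult`` holds the exact ground-truth exposures
    (r-norm 0 by definition of the truth); exactly
    ``exposures_active_per_sample`` entries per sample are positive.
    """
    signatures = generate_signatures(spec)
    n, k = spec.n_samples, spec.n_signatures
    mu, sigma = _lognormal_params(spec.burden_mean, spec.burden_dispersion)
    exposures = np.zeros((n, k))
    counts = np.zeros((n, len(spec.schema)), dtype=np.int64)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    for i in range(n):
        rng = _sample_rng(spec, i)
        active = rng.choice(k, size=spec.exposures_active_per_sample, replace=False)
        weights = rng.dirichlet(np.ones(spec.exposures_active_per_sample))
        burden = float(rng.lognormal(mean=mu, sigma=sigma))
        exposures[i, np.sort(active)] = weights[np.argsort(active)] * burden
        expected = signatures.profiles @ exposures[i]
        if spec.noise == "poisson":
            counts[i] = rng.poisson(expected)
        elif spec.noise == "multinomial":
            total = int(round(burden))
            counts[i] = rng.multinomial(total, expected / expected.sum())
        else:  # "none"
            counts[i] = np.round(expected).astype(np.int64)
    catalog = MutationalCatalog(
        spec.schema, sample_ids, counts,
        metadata={s: {"study": "synthetic"} for s in sample_ids},
    )
    truth = ExposureResult(
        sample_ids=sample_ids,
        signature_ids=list(signatures.signature_ids),
        exposures=exposures,
        rnorm=np.zeros(n),
    )
    return catalog, truth, signatures


def quantize_profiles(signatures: SignatureSet, decimals: int = 3) -> SignatureSet:
    """Round signature profiles onto a 10^-decimals grid (columns still sum to 1).

    Each entry becomes an exact multiple of ``10**-decimals``; the rounding
    remainder of a column is absorbed by its largest entry.  Quantized
    profiles make exactly-representable noiseless catalogs possible: integer
    exposures times ``10**decimals`` yield integer expected counts with no
    rounding at all.
    """
    q = 10 ** decimals
    grid = np.floor(signatures.profiles * q).astype(np.int64)
    for j in range(grid.shape[1]):
        grid[np.argmax(grid[:, j]), j] += q - grid[:, j].sum()
    return SignatureSet(
        signatures.schema,
        list(signatures.signature_ids),
        grid.astype(float) / q,
        metadata={**signatures.metadata, "quantized": f"1e-{decimals}"},
    )


def generate_noiseless_catalog(
    spec: SimulationSpec, decimals: int = 3
) -> tuple[MutationalCatalog, ExposureResult, SignatureSet]:
    """Simulate a catalog whose counts equal signatures · exposures *exactly*.

    Profiles are quantized to the ``10**-decimals`` grid and each active
    exposure is an integer multiple of ``10**decimals``, so the expected
    counts are integers computed in exact integer arithmetic — a catalog a
    perfect refit should reconstruct with zero residual.  ``spec.noise`` is
    ignored (there is none); burdens land near ``burden_mean``.
    """
    signatures = quantize_profiles(generate_signatures(spec), decimals)
    q = 10 ** decimals
    grid = np.round(signatures.profiles * q).astype(np.int64)  # channels × k
    n, k = spec.n_samples, spec.n_signatures
    hi = max(2, int(round(spec.burden_mean / q)))
    exposures = np.zeros((n, k))
    counts = np.zeros((n, len(spec.schema)), dtype=np.int64)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    for i in range(n):
        rng = _sample_rng(spec, i)
        active = rng.choice(k, size=spec.exposures_active_per_sample, replace=False)
        multiples = rng.integers(1, hi + 1, size=spec.exposures_active_per_sample)
        e_int = np.zeros(k, dtype=np.int64)
        e_int[active] = multiples
        counts[i] = grid @ e_int  # exact: integer matmul
        exposures[i] = e_int.astype(float) * q
    catalog = MutationalCatalog(spec.schema, sample_ids, counts)
    truth = ExposureResult(
        sample_ids=sample_ids,
        signature_ids=list(signatures.signature_ids),
        exposures=exposures,
        rnorm=np.zeros(n),
    )
    return catalog, truth, signatures
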