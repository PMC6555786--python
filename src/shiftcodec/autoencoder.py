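"""Per-amino-acid-type autoencoders producing the ShiftCrypt index.

Each amino-acid type gets its own feed-forward autoencoder.  The encoder
takes the residue's scaled chemical shifts (one slot per scheme atom),
passes them through two ReLU hidden layers of ``hidden_size`` neurons
(default 100) and a single sigmoid bottleneck neuron; the decoder mirrors
the encoder and reconstructs the scaled shifts through a sigmoid output
layer, so reconstructions live in the same [0, 1] space as the inputs.
Training minimizes mean squared reconstruction error with Adam and early
stopping on a validation split.

The bottleneck value is the index: strictly in (0, 1), and — because the
sigmoid is bijective — decoded to a unique reconstruction.  Since the
direction the network learns is arbitrary, each model carries an
orientation flag calibrated on helix/sheet-labeled residues so that
sheet-like residues score high and helix-like residues low; when the flag
is set every reported index is ``1 - raw`` and decoding goes through the
same involution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cs_io import (
    AtomScheme,
    ProfileEntry,
    ProteinShiftTable,
    ShiftCryptProfile,
    STANDARD_AA,
    get_scheme,
    select_atoms,
)
from .errors import (
    CalibrationError,
    ConfigMismatchError,
    FittingError,
    ParameterError,
)
from .preprocess import (
    PercentileFilter,
    ShiftScaler,
    complete_case_matrix,
    load_params,
    save_params,
)

CLASSES = ("helix", "sheet", "coil")


@dataclass
class TrainingConfig:
    """Hyperparameters for autoencoder training.

    All values are exposed because the architecture itself fixes only the
    layer sizes and activations; the optimizer settings are conventional
    choices for a model this small.
    """

    learning_rate: float = 1e-3
    max_epochs: int = 500
    batch_size: int = 64
    patience: int = 20
    validation_fraction: float = 0.1
    min_samples: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.validation_fraction <= 0.5:
            raise ParameterError("validation_fraction must be in (0, 0.5]")
        for name in ("max_epochs", "batch_size", "patience", "min_samples"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be a positive integer")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be positive")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class ResidueAutoencoder(TransformerMixin, BaseEstimator):
    """Autoencoder for one amino-acid type.

    Layer stack (encoder then decoder, mirrored):

        n_inputs -> hidden (ReLU) -> hidden (ReLU) -> 1 (sigmoid)
                 -> hidden (ReLU) -> hidden (ReLU) -> n_inputs (sigmoid)

    ``transform`` encodes scaled shift vectors to oriented indices;
    ``inverse_transform`` decodes indices back to scaled shift vectors.

    Attributes
    ----------
    weights_ : list of (W, b) pairs, six layers.
    inverted_ : orientation flag; reported index is ``1 - raw`` when True.
    loss_history_ : per-epoch validation MSE from the last :meth:`fit`.
    """

    #: activation per layer: "relu" or "sigmoid"
    _ACTS = ("relu", "relu", "sigmoid", "relu", "relu", "sigmoid")

    def __init__(
        self,
        residue_type: str = "A",
        hidden_size: int = 100,
        learning_rate: float = 1e-3,
        max_epochs: int = 500,
        batch_size: int = 64,
        patience: int = 20,
        validation_fraction: float = 0.1,
        min_samples: int = 50,
        seed: int = 0,
    ):
        self.residue_type = residue_type
        self.hidden_size = hidden_size
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.min_samples = min_samples
        self.seed = seed

    @classmethod
    def from_config(
        cls, residue_type: str, config: TrainingConfig, hidden_size: int = 100
    ) -> "ResidueAutoencoder":
        kw = asdict(config)
        return cls(residue_type=residue_type, hidden_size=hidden_size, **kw)

    # -- construction -------------------------------------------------------

    def initialize(self, n_inputs: int) -> "ResidueAutoencoder":
        """Build seeded initial weights for ``n_inputs`` scheme atoms."""
        if self.hidden_size < 1:
            raise ParameterError("hidden_size must be >= 1")
        if n_inputs < 1:
            raise ParameterError("n_inputs must be >= 1")
        h = self.hidden_size
        sizes = [n_inputs, h, h, 1, h, h, n_inputs]
        rng = np.random.default_rng(self.seed)
        self.weights_ = []
        for fan_in, fan_out, act in zip(sizes[:-1], sizes[1:], self._ACTS):
            if act == "relu":  # He initialization
                W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out))
            else:  # Glorot for sigmoid layers
                limit = np.sqrt(6.0 / (fan_in + fan_out))
                W = rng.uniform(-limit, limit, (fan_in, fan_out))
            self.weights_.append((W, np.zeros(fan_out)))
        self.n_inputs_ = n_inputs
        self.inverted_ = False
        return self

    @property
    def n_parameters_(self) -> int:
        return sum(W.size + b.size for W, b in self.weights_)

    # -- forward / backward -------------------------------------------------

    def _forward(
        self, X: np.ndarray, weights=None
    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        weights = weights if weights is not None else self.weights_
        acts = [X]
        zs = []
        a = X
        for (W, b), act in zip(weights, self._ACTS):
            z = a @ W + b
            a = np.maximum(z, 0.0) if act == "relu" else _sigmoid(z)
            zs.append(z)
            acts.append(a)
        return zs, acts

    def _raw_encode(self, X: np.ndarray) -> np.ndarray:
        a = np.asarray(X, dtype=float)
        squeeze = a.ndim == 1
        if squeeze:
            a = a[None, :]
        for (W, b), act in zip(self.weights_[:3], self._ACTS[:3]):
            z = a @ W + b
            a = np.maximum(z, 0.0) if act == "relu" else _sigmoid(z)
        out = a[:, 0]
        return out[0] if squeeze else out

    def _raw_decode(self, s: np.ndarray) -> np.ndarray:
        a = np.atleast_1d(np.asarray(s, dtype=float))[:, None]
        for (W, b), act in zip(self.weights_[3:], self._ACTS[3:]):
            z = a @ W + b
            a = np.maximum(z, 0.0) if act == "relu" else _sigmoid(z)
        return a

    def _backward(
        self, X: np.ndarray, zs: list[np.ndarray], acts: list[np.ndarray]
    ) -> list[tuple[np.ndarray, np.ndarray]]:
        """Gradients of mean squared reconstruction error w.r.t. weights."""
        n = X.size
        delta = 2.0 * (acts[-1] - X) / n
        grads: list[tuple[np.ndarray, np.ndarray]] = [None] * 6  # type: ignore
        for layer in range(5, -1, -1):
            act = self._ACTS[layer]
            if act == "sigmoid":
                a = acts[layer + 1]
                dz = delta * a * (1.0 - a)
            else:
                dz = delta * (zs[layer] > 0)
            W, _ = self.weights_[layer]
            grads[layer] = (acts[layer].T @ dz, dz.sum(axis=0))
            delta = dz @ W.T
        return grads

    # -- training -----------------------------------------------------------

    def fit(self, X: np.ndarray, y=None) -> "ResidueAutoencoder":
        """Train on complete, scaled shift vectors (values in [0, 1])."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ParameterError("X must be a 2-D array (n_samples, n_atoms)")
        if len(X) < self.min_samples:
            raise FittingError(
                f"need >= {self.min_samples} complete vectors for "
                f"{self.residue_type}, got {len(X)}"
            )
        if np.isnan(X).any():
            raise ParameterError("training data must be complete (no NaN)")
        if X.min() < 0 or X.max() > 1:
            raise ParameterError("training data must be scaled to [0, 1]")
        self.initialize(X.shape[1])

        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 1]))
        perm = rng.permutation(len(X))
        n_val = max(1, int(round(self.validation_fraction * len(X))))
        X_val, X_train = X[perm[:n_val]], X[perm[n_val:]]

        # Adam state
        m = [(np.zeros_like(W), np.zeros_like(b)) for W, b in self.weights_]
        v = [(np.zeros_like(W), np.zeros_like(b)) for W, b in self.weights_]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        def val_mse() -> float:
            _, acts = self._forward(X_val)
            return float(np.mean((acts[-1] - X_val) ** 2))

        best = val_mse()
        best_weights = [(W.copy(), b.copy()) for W, b in self.weights_]
        self.loss_history_ = [best]
        stall = 0
        for _epoch in range(self.max_epochs):
            order = rng.permutation(len(X_train))
            for start in range(0, len(X_train), self.batch_size):
                batch = X_train[order[start : start + self.batch_size]]
                zs, acts = self._forward(batch)
                grads = self._backward(batch, zs, acts)
                t += 1
                lr_t = self.learning_rate * (
                    np.sqrt(1 - beta2**t) / (1 - beta1**t)
                )
                new_weights = []
                for i, ((W, b), (gW, gb)) in enumerate(zip(self.weights_, grads)):
                    mW, mb = m[i]
                    vW, vb = v[i]
                    mW = beta1 * mW + (1 - beta1) * gW
                    mb = beta1 * mb + (1 - beta1) * gb
                    vW = beta2 * vW + (1 - beta2) * gW**2
                    vb = beta2 * vb + (1 - beta2) * gb**2
                    m[i], v[i] = (mW, mb), (vW, vb)
                    new_weights.append(
                        (
                            W - lr_t * mW / (np.sqrt(vW) + eps),
                            b - lr_t * mb / (np.sqrt(vb) + eps),
                        )
                    )
                self.weights_ = new_weights
            mse = val_mse()
            if not np.isfinite(mse):
                raise FittingError(
                    f"training diverged for {self.residue_type} "
                    f"(non-finite loss); try a lower learning_rate"
                )
            self.loss_history_.append(mse)
            if mse < best - 1e-9:
                best = mse
                best_weights = [(W.copy(), b.copy()) for W, b in self.weights_]
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        self.weights_ = best_weights
        self.final_val_mse_ = best
        return self

    # -- orientation --------------------------------------------------------

    def orient(
        self, X: np.ndarray, labels: Sequence[str], min_per_class: int = 10
    ) -> "ResidueAutoencoder":
        """Set the orientation flag from helix/sheet-labeled vectors.

        After orientation, ``median(index | sheet) >= median(index | helix)``.
        Computed from raw encodings, so applying twice equals applying once.
        """
        labels = np.asarray(labels)
        raw = self._raw_encode(np.asarray(X, dtype=float))
        med = {}
        for cls in ("helix", "sheet"):
            sel = labels == cls
            if sel.sum() < min_per_class:
                raise CalibrationError(
                    f"need >= {min_per_class} {cls}-labeled vectors for "
                    f"{self.residue_type}, got {int(sel.sum())}"
                )
            med[cls] = float(np.median(raw[sel]))
        self.inverted_ = bool(med["sheet"] < med["helix"])
        return self

    # -- inference ----------------------------------------------------------

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Encode scaled shift vectors to oriented indices in (0, 1)."""
        raw = self._raw_encode(X)
        return 1.0 - raw if getattr(self, "inverted_", False) else raw

    encode = transform

    def inverse_transform(self, s: np.ndarray) -> np.ndarray:
        """Decode indices in (0, 1) back to scaled shift vectors."""
        s_arr = np.atleast_1d(np.asarray(s, dtype=float))
        if np.any((s_arr <= 0) | (s_arr >= 1)):
            raise ParameterError("index must lie strictly in (0, 1)")
        if getattr(self, "inverted_", False):
            s_arr = 1.0 - s_arr
        out = self._raw_decode(s_arr)
        return out[0] if np.isscalar(s) or np.ndim(s) == 0 else out

    decode = inverse_transform

    def reconstruction_report(self, X: np.ndarray) -> np.ndarray:
        """Per-atom Pearson r between input and decode(encode(input)).

        Undefined correlations (zero variance on either side) are NaN.
        """
        X = np.asarray(X, dtype=float)
        if len(X) < 10:
            raise ParameterError("need >= 10 held-out vectors")
        recon = self._raw_decode(self._raw_encode(X))
        out = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            a, b = X[:, j], recon[:, j]
            if np.std(a) == 0 or np.std(b) == 0:
                out[j] = np.nan
            else:
                out[j] = np.corrcoef(a, b)[0, 1]
        return out

    # -- persistence --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "params": self.get_params(),
            "n_inputs": self.n_inputs_,
            "inverted": self.inverted_,
            "weights": [[W.tolist(), b.tolist()] for W, b in self.weights_],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ResidueAutoencoder":
        obj = cls(**payload["params"])
        obj.weights_ = [
            (np.asarray(W), np.asarray(b)) for W, b in payload["weights"]
        ]
        obj.n_inputs_ = payload["n_inputs"]
        obj.inverted_ = payload["inverted"]
        return obj


def build_model(
    residue_type: str,
    scheme: str | AtomScheme = "common",
    hidden_size: int = 100,
    seed: int = 0,
    **kwargs,
) -> ResidueAutoencoder:
    """Construct an initialized (untrained) model for one residue type."""
    scheme = scheme if isinstance(scheme, AtomScheme) else get_scheme(scheme)
    n_inputs = len(scheme.atoms(residue_type))
    if n_inputs < 2:
        raise ParameterError(
            f"scheme {scheme.name!r} defines fewer than 2 atoms for "
            f"{residue_type}"
        )
    model = ResidueAutoencoder(
        residue_type=residue_type, hidden_size=hidden_size, seed=seed, **kwargs
    )
    return model.initialize(n_inputs)


# ---------------------------------------------------------------------------
# Whole-protein encoding
# ---------------------------------------------------------------------------

def encode_protein(
    table: ProteinShiftTable,
    registry: Mapping[str, ResidueAutoencoder],
    scheme: AtomScheme,
    scaler: ShiftScaler,
) -> ShiftCryptProfile:
    """Encode every residue of a table into a ShiftCrypt profile.

    Residues whose type has no model are flagged ``unsupported_type``;
    residues missing any scheme atom are flagged ``missing_atoms`` and get
    no index.
    """
    scaler_scheme = scaler.scheme
    scaler_name = (
        scaler_scheme.name if isinstance(scaler_scheme, AtomScheme) else scaler_scheme
    )
    if scaler_name != scheme.name:
        raise ConfigMismatchError(
            f"scaler fitted for scheme {scaler_name!r} but encoding under "
            f"{scheme.name!r}"
        )
    entries = []
    for rec in table:
        model = registry.get(rec.residue_type)
        if model is None:
            entries.append(
                ProfileEntry(
                    rec.chain_id, rec.residue_number, rec.residue_type,
                    None, "unsupported_type",
                )
            )
            continue
        vals, mask = select_atoms(rec, scheme)
        if mask.any():
            entries.append(
                ProfileEntry(
                    rec.chain_id, rec.residue_number, rec.residue_type,
                    None, "missing_atoms",
                )
            )
            continue
        scaled = scaler.scale(vals, residue_type=rec.residue_type)
        idx = float(model.transform(scaled))
        entries.append(
            ProfileEntry(
                rec.chain_id, rec.residue_number, rec.residue_type, idx, "ok"
            )
        )
    return ShiftCryptProfile(table.entry_id, entries)


class ShiftCrypt(TransformerMixin, BaseEstimator):
    """End-to-end estimator: filter, scale, train one model per residue type.

    ``fit`` takes a pool of :class:`ProteinShiftTable` plus (optionally) a
    helix/sheet/coil label map used to orient each model; ``transform``
    turns a table into a :class:`ShiftCryptProfile`.

    Parameters mirror :class:`TrainingConfig` plus the scheme and the
    percentile-filter bounds.
    """

    def __init__(
        self,
        scheme: str = "common",
        hidden_size: int = 100,
        learning_rate: float = 1e-3,
        max_epochs: int = 500,
        batch_size: int = 64,
        patience: int = 20,
        validation_fraction: float = 0.1,
        min_samples: int = 50,
        lower: float = 1.0,
        upper: float = 99.0,
        seed: int = 0,
    ):
        self.scheme = scheme
        self.hidden_size = hidden_size
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.min_samples = min_samples
        self.lower = lower
        self.upper = upper
        self.seed = seed

    def _scheme(self) -> AtomScheme:
        return get_scheme(self.scheme)

    def fit(
        self,
        tables: Iterable[ProteinShiftTable],
        labels: Mapping[tuple[str, str, int], str] | None = None,
    ) -> "ShiftCrypt":
        """Fit filter, scaler and per-type autoencoders on a training pool.

        ``labels`` maps (entry_id, chain_id, residue_number) to a class in
        {helix, sheet, coil}; when given, each trained model is oriented so
        sheet-labeled residues score high.
        """
        scheme = self._scheme()
        tables = list(tables)
        records = [rec for t in tables for rec in t]
        self.filter_ = PercentileFilter(
            scheme=scheme, lower=self.lower, upper=self.upper
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.filter_.fit(records)
        kept_keys: set[tuple[str, str, int]] = set()
        kept: list = []
        for table in tables:
            for rec in table:
                if not self.filter_.is_outlier(rec):
                    kept.append(rec)
                    kept_keys.add((table.entry_id, rec.chain_id, rec.residue_number))
        self.scaler_ = ShiftScaler(scheme=scheme).fit(kept)

        # Complete-case scaled matrices and (optional) labels per type
        label_of: dict[tuple[str, str, int], str] = dict(labels or {})
        X_by_type: dict[str, list[np.ndarray]] = {}
        lab_by_type: dict[str, list[str]] = {}
        for table in tables:
            for rec in table:
                key = (table.entry_id, rec.chain_id, rec.residue_number)
                if key not in kept_keys:
                    continue
                vals, mask = select_atoms(rec, scheme)
                if mask.any():
                    continue
                scaled = self.scaler_.scale(vals, residue_type=rec.residue_type)
                X_by_type.setdefault(rec.residue_type, []).append(scaled)
                lab_by_type.setdefault(rec.residue_type, []).append(
                    label_of.get(key, "")
                )

        self.models_ = {}
        for i, rtype in enumerate(STANDARD_AA):
            rows = X_by_type.get(rtype)
            if rows is None or len(rows) < self.min_samples:
                continue
            X = np.vstack(rows)
            model = ResidueAutoencoder(
                residue_type=rtype,
                hidden_size=self.hidden_size,
                learning_rate=self.learning_rate,
                max_epochs=self.max_epochs,
                batch_size=self.batch_size,
                patience=self.patience,
                validation_fraction=self.validation_fraction,
                min_samples=self.min_samples,
                seed=int(np.random.SeedSequence([self.seed, i]).generate_state(1)[0] % (2**31)),
            )
            model.fit(X)
            labs = np.asarray(lab_by_type[rtype])
            if labels is not None and {"helix", "sheet"} <= set(labs):
                sel = np.isin(labs, ("helix", "sheet"))
                try:
                    model.orient(X[sel], labs[sel])
                except CalibrationError:
                    pass  # too few labeled residues of one class; leave raw
            self.models_[rtype] = model
        if not self.models_:
            raise FittingError(
                "no residue type had enough complete vectors to train"
            )
        return self

    def transform(self, table: ProteinShiftTable) -> ShiftCryptProfile:
        """Encode one protein's shift table into an index profile."""
        return encode_protein(table, self.models_, self._scheme(), self.scaler_)

    encode = transform

    # -- bundle persistence -------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write a model bundle: manifest, filter/scaler params, weights."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format": "shiftcodec-bundle/1",
            "scheme": self.scheme,
            "params": self.get_params(),
            "residue_types": sorted(self.models_),
            "orientation": {t: m.inverted_ for t, m in self.models_.items()},
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
        save_params(directory / "preprocess.json", self.filter_, self.scaler_)
        for rtype, model in self.models_.items():
            (directory / f"model_{rtype}.json").write_text(
                json.dumps(model.to_dict())
            )

    @classmethod
    def load(cls, directory: str | Path) -> "ShiftCrypt":
        directory = Path(directory)
        manifest_path = directory / "manifest.json"
        if not manifest_path.exists():
            raise ParameterError(f"{directory} is not a model bundle")
        manifest = json.loads(manifest_path.read_text())
        obj = cls(**manifest["params"])
        obj.filter_, obj.scaler_ = load_params(directory / "preprocess.json")
        scaler_scheme = obj.scaler_.scheme
        if scaler_scheme != manifest["scheme"]:
            raise ConfigMismatchError(
                f"bundle manifest scheme {manifest['scheme']!r} does not "
                f"match scaler scheme {scaler_scheme!r}"
            )
        obj.models_ = {}
        for rtype in manifest["residue_types"]:
            payload = json.loads((directory / f"model_{rtype}.json").read_text())
            obj.models_[rtype] = ResidueAutoencoder.from_dict(payload)
        return obj


def encode_with_fallback(
    table: ProteinShiftTable, bundles: Sequence[ShiftCrypt]
) -> ShiftCryptProfile:
    """Encode with the first bundle; fill missing-atom residues from later
    bundles (typically common then minimal schemes)."""
    if not bundles:
        raise ParameterError("need at least one bundle")
    profile = bundles[0].transform(table)
    for bundle in bundles[1:]:
        if all(e.status == "ok" for e in profile.entries):
            break
        alt = bundle.transform(table)
        for i, entry in enumerate(profile.entries):
            if entry.status == "missing_atoms" and alt.entries[i].status == "ok":
                profile.entries[i] = alt.entries[i]
    return profile


# ---------------------------------------------------------------------------
# Stability scan
# ---------------------------------------------------------------------------

DEFAULT_HIDDEN_GRID = tuple(range(10, 151, 10))  # 15 sizes


def stability_scan(
    X: np.ndarray,
    labels: Sequence[str],
    hidden_sizes: Sequence[int] = DEFAULT_HIDDEN_GRID,
    residue_type: str = "A",
    seed: int = 0,
    **train_kwargs,
) -> pd.DataFrame:
    """Train one model per hidden size and report per-class index medians.

    For each hidden size the model is trained on ``X`` (scaled complete
    vectors of one residue type), oriented on the labeled subset, and the
    median oriented index per class is recorded.  A stable model family
    shows little variation of these medians across sizes.
    """
    labels = np.asarray(labels)
    rows = []
    for h in hidden_sizes:
        try:
            model = ResidueAutoencoder(
                residue_type=residue_type, hidden_size=int(h), seed=seed,
                **train_kwargs,
            )
            model.fit(X)
            sel = np.isin(labels, ("helix", "sheet"))
            model.orient(X[sel], labels[sel])
            idx = model.transform(X)
        except Exception as exc:
            raise FittingError(f"hidden_size={h}: {exc}") from exc
        row = {"hidden_size": int(h)}
        for cls in CLASSES:
            mask = labels == cls
            row[f"median_{cls}"] = (
                float(np.median(idx[mask])) if mask.any() else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("hidden_size")
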