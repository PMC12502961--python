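"""Splitting, multi-task training, metrics and learning curves.

Training minimizes the mean squared error averaged over the five z-scored
targets (per-property standardization by training-set mean/sd), using Adam
with minibatches and early stopping on the summed validation loss; the
parameters of the best validation epoch are returned.  Every artifact is a
pure function of (data, config, seeds).  Metrics (MAE, RMSE, R²) are always
reported in the original property units.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .egat import EGATConfig, EGATModel, GraphBatch
from .featurize import FeatureScheme, MolecularGraph, featurize, scheme_dims
from .fixtures import PROPERTY_COLUMNS, MoleculeRecord

PROPERTY_NAMES = ("gap", "ip", "ea", "eox", "ered")

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "TargetScaler",
    "TrainedModel",
    "split_dataset",
    "train_model",
    "evaluate",
    "compute_metrics",
    "learning_curve",
    "metrics_by_ring_count",
    "top_k_errors",
]


@dataclass(frozen=True)
class SplitSpec:
    n_train: int
    n_val: int
    n_test: int
    seed: int = 0

    @property
    def total(self) -> int:
        return self.n_train + self.n_val + self.n_test


def split_dataset(n_records: int, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random disjoint train/val/test index sets of the exact requested sizes."""
    if spec.total > n_records:
        raise ValueError(
            f"split sizes {spec.n_train}+{spec.n_val}+{spec.n_test} exceed dataset size {n_records}"
        )
    if min(spec.n_train, spec.n_val, spec.n_test) < 0:
        raise ValueError("split sizes must be nonnegative")
    perm = np.random.default_rng(spec.seed).permutation(n_records)
    train = np.sort(perm[: spec.n_train])
    val = np.sort(perm[spec.n_train : spec.n_train + spec.n_val])
    test = np.sort(perm[spec.n_train + spec.n_val : spec.total])
    return train, val, test


class TargetScaler:
    """Per-property z-scoring fitted on training targets only."""

    def __init__(self, train_targets: np.ndarray):
        y = np.asarray(train_targets, dtype=np.float64)
        if y.ndim != 2 or y.shape[0] < 2:
            raise ValueError("need a (n >= 2, n_properties) training target matrix")
        if not np.all(np.isfinite(y)):
            raise ValueError("training targets must be finite (fully labeled)")
        self.mean = y.mean(axis=0)
        self.sd = y.std(axis=0, ddof=0)
        zero = np.where(self.sd == 0)[0]
        if zero.size:
            names = [PROPERTY_NAMES[i] if i < len(PROPERTY_NAMES) else str(i) for i in zero]
            raise ValueError(f"zero-variance training propert{'y' if len(names)==1 else 'ies'}: {names}")

    def transform(self, y: np.ndarray) -> np.ndarray:
        return (y - self.mean) / self.sd

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return z * self.sd + self.mean


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol (adaptive-moment gradient descent)."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 60
    patience: int = 15
    seed: int = 0

    def validate(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs, self.patience) <= 0:
            raise ValueError("all training hyperparameters must be positive")


@dataclass
class TrainedModel:
    """Checkpointable bundle: architecture, feature scheme, scaler, parameters."""

    egat_config: EGATConfig
    scheme: FeatureScheme
    params: np.ndarray
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    version: str = "1"

    @property
    def model(self) -> EGATModel:
        f_n, f_e = scheme_dims(self.scheme)
        return EGATModel(self.egat_config, f_n, f_e)

    def predict(self, graphs: list[MolecularGraph], batch_size: int = 256):
        """(predictions in original units (M, 5), embeddings (M, hidden))."""
        model = self.model
        params = self.params.astype(np.float64)
        preds, embs = [], []
        for i in range(0, len(graphs), batch_size):
            p, e = model.forward(GraphBatch(graphs[i : i + batch_size]), params)
            preds.append(p)
            embs.append(e)
        z = np.concatenate(preds)
        return z * self.scaler_sd + self.scaler_mean, np.concatenate(embs)

    def save(self, path) -> None:
        header = dict(
            version=self.version,
            egat_config=asdict(self.egat_config),
            scheme=dict(element_palette=list(self.scheme.element_palette),
                        version=self.scheme.version),
        )
        np.savez(
            path,
            header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
            params=self.params,
            scaler_mean=self.scaler_mean,
            scaler_sd=self.scaler_sd,
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path) as data:
            header = json.loads(bytes(data["header"]).decode())
            cfgd = header["egat_config"]
            cfgd["head_dims"] = tuple(cfgd["head_dims"])
            scheme = FeatureScheme(
                element_palette=tuple(header["scheme"]["element_palette"]),
                version=header["scheme"]["version"],
            )
            return cls(
                egat_config=EGATConfig(**cfgd),
                scheme=scheme,
                params=data["params"],
                scaler_mean=data["scaler_mean"],
                scaler_sd=data["scaler_sd"],
                version=header["version"],
            )


def featurize_records(records: list[MoleculeRecord], scheme: FeatureScheme | None = None):
    scheme = scheme or FeatureScheme()
    return [featurize(r.smiles, scheme, r.mol_id) for r in records]


def train_model(
    graphs: list[MolecularGraph],
    labels: np.ndarray,
    split: tuple[np.ndarray, np.ndarray, np.ndarray] | SplitSpec,
    train_config: TrainConfig | None = None,
    egat_config: EGATConfig | None = None,
    scheme: FeatureScheme | None = None,
) -> tuple[TrainedModel, pd.DataFrame]:
    """Train the regressor; returns the best-validation-epoch checkpoint and
    the per-epoch loss history.

    ``labels`` is an (n_graphs, 5) array in original units.  Fully
    reproducible given the seeds in the two configs.
    """
    tc = train_config or TrainConfig()
    tc.validate()
    ec = egat_config or EGATConfig()
    scheme = scheme or FeatureScheme()
    if isinstance(split, SplitSpec):
        split = split_dataset(len(graphs), split)
    train_idx, val_idx, _ = split
    labels = np.asarray(labels, dtype=np.float64)
    if not np.all(np.isfinite(labels[np.concatenate([train_idx, val_idx])])):
        raise ValueError("all training and validation molecules must be labeled")
    scaler = TargetScaler(labels[train_idx])
    y = scaler.transform(labels)

    f_n, f_e = scheme_dims(scheme)
    model = EGATModel(ec, f_n, f_e)
    params = model.init_params(ec.seed).astype(np.float32)

    rng = np.random.default_rng(tc.seed)
    drop_rng = np.random.default_rng(tc.seed + 1)
    # Adam state
    m = np.zeros_like(params)
    v = np.zeros_like(params)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    val_batch = GraphBatch([graphs[i] for i in val_idx])
    y_val = y[val_idx].astype(np.float32)

    best_val = np.inf
    best_params = params.copy()
    since_best = 0
    history = []
    for epoch in range(tc.max_epochs):
        order = rng.permutation(train_idx)
        train_losses = []
        for start in range(0, len(order), tc.batch_size):
            idx = order[start : start + tc.batch_size]
            batch = GraphBatch([graphs[i] for i in idx])
            loss, grad = model.loss_and_grad(
                batch, y[idx].astype(np.float32), params,
                training=True, dropout_rng=drop_rng,
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, step {step}: {loss}; "
                    f"|params|_max={np.abs(params).max():.3g}"
                )
            train_losses.append(loss)
            step += 1
            m = beta1 * m + (1 - beta1) * grad
            v = beta2 * v + (1 - beta2) * grad**2
            mh = m / (1 - beta1**step)
            vh = v / (1 - beta2**step)
            params = params - tc.learning_rate * mh / (np.sqrt(vh) + eps)
        val_preds, _ = model.forward(val_batch, params)
        val_loss = float(np.mean((val_preds - y_val) ** 2))
        history.append(
            dict(epoch=epoch, train_loss=float(np.mean(train_losses)), val_loss=val_loss)
        )
        if val_loss < best_val:
            best_val = val_loss
            best_params = params.copy()
            since_best = 0
        else:
            since_best += 1
            if since_best >= tc.patience:
                break
    trained = TrainedModel(
        egat_config=ec,
        scheme=scheme,
        params=best_params,
        scaler_mean=scaler.mean,
        scaler_sd=scaler.sd,
    )
    return trained, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def compute_metrics(predictions: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Per-property MAE/RMSE/R² table (R² against the evaluation-set mean)."""
    predictions = np.asarray(predictions, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if predictions.shape != labels.shape or predictions.shape[0] == 0:
        raise ValueError("predictions and labels must be equal-shaped and non-empty")
    resid = predictions - labels
    mae = np.abs(resid).mean(axis=0)
    rmse = np.sqrt((resid**2).mean(axis=0))
    ss_res = (resid**2).sum(axis=0)
    ss_tot = ((labels - labels.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    return pd.DataFrame(
        {"MAE": mae, "RMSE": rmse, "R2": r2}, index=list(PROPERTY_NAMES[: labels.shape[1]])
    )


def evaluate(
    trained: TrainedModel,
    graphs: list[MolecularGraph],
    labels: np.ndarray,
) -> pd.DataFrame:
    """Metrics of a trained model on a labeled evaluation set (original units)."""
    if len(graphs) == 0:
        raise ValueError("empty evaluation set")
    preds, _ = trained.predict(graphs)
    return compute_metrics(preds, labels)


def learning_curve(
    graphs: list[MolecularGraph],
    labels: np.ndarray,
    sizes: list[int],
    split: tuple[np.ndarray, np.ndarray, np.ndarray],
    train_config: TrainConfig | None = None,
    egat_config: EGATConfig | None = None,
    scheme: FeatureScheme | None = None,
) -> pd.DataFrame:
    """Test-set MAE as a function of training-set size.

    Training subsets are nested (smaller sets are prefixes of larger ones,
    drawn from a fixed shuffle of the training pool); validation and test
    sets stay fixed, and every run uses identical seeds.
    """
    if sorted(sizes) != list(sizes):
        raise ValueError("sizes must be ascending")
    train_pool, val_idx, test_idx = split
    if sizes[-1] > len(train_pool):
        raise ValueError(f"largest size {sizes[-1]} exceeds training pool {len(train_pool)}")
    tc = train_config or TrainConfig()
    pool = np.random.default_rng(tc.seed).permutation(train_pool)
    rows = []
    for size in sizes:
        sub = np.sort(pool[:size])
        trained, _ = train_model(
            graphs, labels, (sub, val_idx, test_idx), tc, egat_config, scheme
        )
        metrics = evaluate(trained, [graphs[i] for i in test_idx], labels[test_idx])
        row = {"size": size}
        row.update({f"mae_{p}": metrics.loc[p, "MAE"] for p in metrics.index})
        rows.append(row)
    return pd.DataFrame(rows)


def metrics_by_ring_count(
    trained: TrainedModel,
    records: list[MoleculeRecord],
    graphs: list[MolecularGraph],
    labels: np.ndarray,
) -> pd.DataFrame:
    """Metrics stratified by SSSR ring count, with group sizes."""
    preds, _ = trained.predict(graphs)
    ring_counts = np.array([r.ring_count for r in records])
    frames = []
    for rc in sorted(set(ring_counts)):
        mask = ring_counts == rc
        if not mask.any():
            warnings.warn(f"no molecules with ring count {rc}; group omitted")
            continue
        m = compute_metrics(preds[mask], labels[mask])
        m.insert(0, "ring_count", rc)
        m.insert(1, "n", int(mask.sum()))
        frames.append(m.reset_index(names="property"))
    return pd.concat(frames, ignore_index=True)


def top_k_errors(
    trained: TrainedModel,
    records: list[MoleculeRecord],
    graphs: list[MolecularGraph],
    labels: np.ndarray,
    property_name: str,
    k: int = 10,
) -> pd.DataFrame:
    """The k molecules with the largest absolute errors for one property,
    descending; ties broken by mol_id."""
    if k > len(records):
        raise ValueError(f"k={k} exceeds evaluation-set size {len(records)}")
    col = PROPERTY_NAMES.index(property_name)
    preds, _ = trained.predict(graphs)
    err = np.abs(preds[:, col] - labels[:, col])
    df = pd.DataFrame(
        {
            "mol_id": [r.mol_id for r in records],
            "smiles": [r.smiles for r in records],
            "label": labels[:, col],
            "prediction": preds[:, col],
            "abs_error": err,
        }
    )
    df = df.sort_values(["abs_error", "mol_id"], ascending=[False, True], kind="stable")
    return df.head(k).reset_index(drop=True)
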