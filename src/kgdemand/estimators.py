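"""Scikit-learn style interface to the GCN-LSTM forecaster.

:class:`KGGCNLSTMForecaster` is a regressor over graph-window sample tensors
(B, T_w, N, F): ``fit`` trains with Adam, full-batch by default, with
early stopping on a held-out chronological validation set; ``predict``
returns one-step demand forecasts. The estimator composes with sklearn
(``get_params``/``set_params``/``clone``); ablation variants are reachable
through constructor knobs (``gcn_layers``, ``clip``, ``temporal``, ...).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import model_core
from .model_core import AdamOptimizer, ForecastNetwork, init_model_params, mse_loss

__all__ = ["KGGCNLSTMForecaster"]


class KGGCNLSTMForecaster(RegressorMixin, BaseEstimator):
    """One-step demand forecaster for a single target drug.

    Parameters
    ----------
    adjacency : (N, N) array
        Binary symmetric adjacency of the target's k-hop subgraph (no
        self-loops; they are added during normalisation). ``None`` is only
        valid when fitting from a list of :class:`GraphWindowSample`, which
        carries its own adjacency.
    target_position : int
        Row of the target drug in the subgraph node order.
    gcn_layers : int
        GCN depth; 0 removes the GCN entirely (the temporal model then reads
        the target's raw window — the LSTM-only ablation).
    clip : bool
        Keep only the target row after the GCN (the reference model). When
        False, node embeddings are pooled per snapshot instead.
    pool : {"mean", "sum"}
        Aggregation used by the no-clip variant.
    temporal : {"lstm", "mlp"}
        Temporal module: single-layer LSTM or one-hidden-layer perceptron.
    hidden_dim, gcn_hidden : int
        LSTM/MLP hidden size and GCN embedding width (reference: 64 both).
    learning_rate, dropout, patience, max_epochs, tol
        Adam step size, dropout rate, early-stopping patience in epochs,
        epoch cap, and the minimum validation-loss decrease that counts as
        an improvement.
    batch_size : int or None
        Mini-batch size; ``None`` trains full-batch.
    random_state : int or None
        Seeds initialisation, dropout, and mini-batch shuffling.

    Attributes
    ----------
    network_ : ForecastNetwork
        Trained network holding the best-validation-loss weights.
    loss_curve_ : list of float
        Training loss per epoch.
    val_loss_curve_ : list of float
        Validation loss per epoch (training loss when no validation data).
    n_iter_ : int
        Number of completed epochs.
    best_val_loss_ : float
    """

    def __init__(
        self,
        adjacency=None,
        target_position: int = 0,
        *,
        gcn_layers: int = 2,
        clip: bool = True,
        pool: str = "mean",
        temporal: str = "lstm",
        hidden_dim: int = 64,
        gcn_hidden: int = 64,
        learning_rate: float = 1e-3,
        dropout: float = 0.2,
        patience: int = 500,
        max_epochs: int = 5000,
        tol: float = 1e-8,
        batch_size: int | None = None,
        random_state: int | None = None,
    ) -> None:
        self.adjacency = adjacency
        self.target_position = target_position
        self.gcn_layers = gcn_layers
        self.clip = clip
        self.pool = pool
        self.temporal = temporal
        self.hidden_dim = hidden_dim
        self.gcn_hidden = gcn_hidden
        self.learning_rate = learning_rate
        self.dropout = dropout
        self.patience = patience
        self.max_epochs = max_epochs
        self.tol = tol
        self.batch_size = batch_size
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _coerce(self, X, y=None):
        """Accept a (B, T, N, F) array or a list of GraphWindowSample."""
        if isinstance(X, (list, tuple)) and X and hasattr(X[0], "snapshot_features"):
            from .preprocessing import stack_samples

            arr, targets = stack_samples(list(X))
            adjacency = X[0].adjacency_ref
            position = X[0].target_position
            if y is None:
                y = targets
            return arr, (None if y is None else np.asarray(y, float)), adjacency, position
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 4:
            raise ValueError(f"X must be (B, T, N, F), got shape {arr.shape}")
        if self.adjacency is None:
            raise ValueError("adjacency must be given when X is a raw tensor")
        return arr, (None if y is None else np.asarray(y, float)), self.adjacency, self.target_position

    def fit(self, X, y=None, X_val=None, y_val=None):
        """Train with Adam and patience-based early stopping.

        Validation loss is evaluated after every epoch with dropout off; the
        weights returned are the ones achieving the best validation loss.
        Without validation data the training loss takes its place.
        """
        X, y, adjacency, position = self._coerce(X, y)
        if y is None or y.size == 0:
            raise ValueError("fit needs targets")
        if X_val is not None:
            X_val, y_val, _, _ = self._coerce(X_val, y_val)
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")

        a_hat = model_core.normalize_adjacency(np.asarray(adjacency, float)).propagation_matrix
        n_features = X.shape[3]
        ss = np.random.SeedSequence(self.random_state)
        init_rng, drop_rng, shuffle_rng = (np.random.default_rng(c) for c in ss.spawn(3))

        params = init_model_params(
            init_rng,
            n_features=n_features,
            gcn_layers=self.gcn_layers,
            gcn_hidden=self.gcn_hidden,
            hidden_dim=self.hidden_dim,
            temporal=self.temporal,
            dropout_rate=self.dropout,
        )
        net = ForecastNetwork(params, clip=self.clip, pool=self.pool)
        optimizer = AdamOptimizer(net.parameter_dict(), learning_rate=self.learning_rate)

        def val_loss() -> float:
            if X_val is None:
                pred, _ = net.forward(X, a_hat, position, train=False)
                return mse_loss(pred, y)
            pred, _ = net.forward(X_val, a_hat, position, train=False)
            return mse_loss(pred, y_val)

        best = val_loss()
        best_weights = {k: v.copy() for k, v in net.parameter_dict().items()}
        since_improve = 0
        self.loss_curve_: list[float] = []
        self.val_loss_curve_: list[float] = []
        n = X.shape[0]
        batch = n if self.batch_size is None else min(self.batch_size, n)
        epoch = 0
        for epoch in range(1, self.max_epochs + 1):
            order = shuffle_rng.permutation(n) if batch < n else np.arange(n)
            epoch_losses = []
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                loss, grads = net.loss_and_grads(
                    X[idx], y[idx], a_hat, position, train=True, rng=drop_rng
                )
                if not np.isfinite(loss):
                    raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
                optimizer.step(grads)
                epoch_losses.append(loss)
            self.loss_curve_.append(float(np.mean(epoch_losses)))
            current = val_loss()
            self.val_loss_curve_.append(current)
            if current < best - self.tol:
                best = current
                best_weights = {k: v.copy() for k, v in net.parameter_dict().items()}
                since_improve = 0
            else:
                since_improve += 1
            if since_improve >= self.patience:
                break

        net.set_parameters(best_weights)
        self.network_ = net
        self.a_hat_ = a_hat
        self.position_ = position
        self.best_val_loss_ = best
        self.n_iter_ = epoch
        self.n_features_in_ = n_features
        return self

    def predict(self, X):
        """One-step forecasts (always non-negative) for a sample tensor."""
        if not hasattr(self, "network_"):
            raise RuntimeError("estimator is not fitted")
        X, _, _, _ = self._coerce(X)
        pred, _ = self.network_.forward(X, self.a_hat_, self.position_, train=False)
        return pred

    def count_parameters(self) -> dict[str, int]:
        """Per-block trainable parameter counts of the fitted network."""
        if not hasattr(self, "network_"):
            raise RuntimeError("estimator is not fitted")
        return model_core.count_parameters(self.network_.params)
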