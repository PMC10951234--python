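"""Multitask stress classifier: LSTM autoencoder backbone with per-subject heads.

The model treats each subject-day as a 24-step sequence of flattened hourly
histograms.  A one-layer LSTM encoder produces a latent state (the last
hidden state); a one-layer LSTM decoder reconstructs the input sequence
from the encoder's hidden states, and the mean absolute reconstruction
error (RE) acts as a denoising regularizer.  The latent state, concatenated
with day-level covariates, feeds a shared fully connected layer and then a
two-layer MLP head per subject (multitask personalization).  A *generic*
head trained on everyone provides cold-start predictions for subjects with
no data.

Training minimizes the integrated loss

    L = alpha * RE + beta * CE_personal [+ lambda * CE_generic]

with alpha = 1e-4 and beta = 1 by default; lambda defaults to one over the
number of training subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor, concat, cross_entropy, softmax, take_rows, Adam, Linear, LSTM, Module

logger = logging.getLogger(__name__)

N_CLASSES = 3
GENERIC = "__generic__"
POOLED = "__pooled__"


@dataclass
class BackboneConfig:
    """Architecture hyper-parameters.

    ``latent_dim`` is the encoder's hidden size (the latent representation
    is the last hidden state).  Only the LSTM backbone is implemented; the
    field exists so alternative sequence encoders can be slotted in.
    """

    latent_dim: int = 128
    shared_width: int = 64
    head_hidden: int = 32
    backbone_kind: str = "lstm"

    def __post_init__(self):
        if self.latent_dim <= 0:
            raise ValueError("latent_dim must be positive")
        if self.backbone_kind != "lstm":
            raise NotImplementedError(f"backbone {self.backbone_kind!r} not available")


@dataclass
class LossWeights:
    """Weights of the integrated loss (alpha: RE, beta: personal CE,
    lam: generic CE; lam defaults to 1/n_training_subjects at fit time)."""

    alpha: float = 1e-4
    beta: float = 1.0
    lam: float | None = None

    def __post_init__(self):
        if not (0 <= self.alpha <= 1 and 0 <= self.beta <= 1):
            raise ValueError("alpha and beta must lie in [0, 1]")
        if self.lam is not None and self.lam <= 0:
            raise ValueError("lambda must be positive")


def generic_loss_weight(n_training_subjects: int) -> float:
    """Default generic-head weight: one over the number of training
    subjects (excluding any incoming subject)."""
    if n_training_subjects < 1:
        raise ValueError("need at least one training subject")
    return 1.0 / n_training_subjects


@dataclass
class LossTerms:
    re: float
    ce_personal: float
    ce_generic: float = 0.0


def integrated_loss(terms: LossTerms, w: LossWeights, with_generic: bool = False):
    """alpha*RE + beta*CE_personal (+ lambda*CE_generic).  Works on floats
    and on autograd tensors alike."""
    if w.alpha < 0 or w.beta < 0 or (w.lam is not None and w.lam < 0):
        raise ValueError("loss weights must be non-negative")
    total = w.alpha * terms.re + w.beta * terms.ce_personal
    if with_generic:
        if w.lam is None:
            raise ValueError("lambda not set; call generic_loss_weight first")
        total = total + w.lam * terms.ce_generic
    return total


def merge_to_binary(p: np.ndarray) -> np.ndarray:
    """Collapse 3-class probabilities to binary stress detection.

    The positive class pools the median and above-median classes, so the
    model can be trained on the finer 3-level labels and still serve a
    binary detector.
    """
    p = np.asarray(p, dtype=float)
    squeeze = p.ndim == 1
    p = np.atleast_2d(p)
    out = np.stack([p[:, 0], p[:, 1] + p[:, 2]], axis=1)
    return out[0] if squeeze else out


class Head(Module):
    """Two-layer MLP head: ReLU hidden layer, linear output to 3 logits."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(n_in, n_hidden, rng)
        self.fc2 = Linear(n_hidden, N_CLASSES, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())

    def copy_from(self, other: "Head") -> None:
        self.fc1.copy_from(other.fc1)
        self.fc2.copy_from(other.fc2)


class StressModel(Module):
    """CALM-style multitask model.

    ``head_map`` routes each subject to a head key: the identity map gives
    one head per subject (full personalization); a constant map gives the
    pooled single-head baseline; a survey-cluster map gives group heads.
    With the identity map a clustered model whose groups are singletons is
    forward-pass identical to the personalized model.
    """

    def __init__(self, n_channels: int, n_bins: int, n_covariates: int,
                 subjects: list[str], config: BackboneConfig | None = None,
                 seed: int = 0, head_map: dict[str, str] | None = None):
        self.config = config or BackboneConfig()
        self.n_channels = n_channels
        self.n_bins = n_bins
        self.n_covariates = n_covariates
        rng = np.random.default_rng(seed)
        d_in = n_channels * n_bins
        L = self.config.latent_dim
        self.encoder = LSTM(d_in, L, rng)
        self.decoder = LSTM(L, L, rng)
        self.decoder_proj = Linear(L, d_in, rng)
        self.shared = Linear(L + n_covariates, self.config.shared_width, rng)
        self.head_map = dict(head_map) if head_map is not None else {s: s for s in subjects}
        for s in subjects:
            self.head_map.setdefault(s, s)
        head_keys = sorted(set(self.head_map.values()))
        self.heads: dict[str, Head] = {
            k: Head(self.config.shared_width, self.config.head_hidden, rng) for k in head_keys
        }
        self.generic_head = Head(self.config.shared_width, self.config.head_hidden, rng)
        self._rng = rng

    # ------------------------------------------------------------------ #
    def _steps(self, X: np.ndarray) -> list[Tensor]:
        """Flatten (B, C, 24, H) into 24 time steps of (B, C*H)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X[None]
        if not np.all(np.isfinite(X)):
            raise ValueError("input tensor contains non-finite values")
        B = X.shape[0]
        return [Tensor(X[:, :, t, :].reshape(B, -1)) for t in range(X.shape[2])]

    def encode(self, X: np.ndarray) -> tuple[Tensor, list[Tensor]]:
        """Return (latent = last hidden state, all 24 hidden states)."""
        hs, h_last = self.encoder(self._steps(X))
        return h_last, hs

    def decode(self, hidden_states: list[Tensor]) -> list[Tensor]:
        """Reconstruct the flattened input sequence from encoder states."""
        dec_hs, _ = self.decoder(hidden_states)
        return [self.decoder_proj(h) for h in dec_hs]

    def reconstruction_error(self, X: np.ndarray, recon: list[Tensor]) -> Tensor:
        """Mean absolute error between input sequence and reconstruction."""
        steps = self._steps(X)
        total = None
        for x_t, r_t in zip(steps, recon):
            term = (r_t - x_t).abs().mean()
            total = term if total is None else total + term
        return total * (1.0 / len(steps))

    def shared_features(self, latent: Tensor, covariates: np.ndarray) -> Tensor:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        return self.shared(concat([latent, Tensor(cov)], axis=1)).relu()

    def head_input(self, feats: Tensor, subject_idx: np.ndarray,
                   train_mode: bool = False) -> Tensor:
        """Representation consumed by the personal heads; the branched
        subclass overrides this with the branch mixture."""
        return feats

    # ------------------------------------------------------------------ #
    def logits_for(self, feats: Tensor, subjects: np.ndarray,
                   train_mode: bool = False) -> Tensor:
        """Per-subject head logits for a batch (rows grouped internally)."""
        subjects = np.asarray(subjects)
        subj_idx = np.array([self.subject_index(s) for s in subjects])
        hin = self.head_input(feats, subj_idx, train_mode=train_mode)
        out = np.empty((len(subjects), N_CLASSES))
        pieces = []
        keys = np.array([self.head_map[s] for s in subjects])
        for key in np.unique(keys):
            rows = np.where(keys == key)[0]
            pieces.append((rows, self.heads[key](take_rows(hin, rows))))
        # reassemble in original row order (differentiably, via scatter in backward)
        return _scatter_rows(pieces, len(subjects))

    def subject_index(self, subject: str) -> int:
        # plain model has no per-subject selection parameters
        return 0

    def classify(self, X: np.ndarray, covariates: np.ndarray,
                 subjects: np.ndarray | None = None,
                 generic: bool = False) -> np.ndarray:
        """Class probabilities from the chosen head (softmax outputs).

        Unknown subjects raise a cold-start error directing the caller to
        the generic head unless ``generic=True``.
        """
        latent, _ = self.encode(X)
        feats = self.shared_features(latent, covariates)
        if generic:
            logits = self.generic_head(feats)
        else:
            if subjects is None:
                raise ValueError("subjects required unless generic=True")
            unknown = [s for s in np.asarray(subjects) if s not in self.head_map]
            if unknown:
                raise ColdStartError(
                    f"no personal head for {sorted(set(map(str, unknown)))}; "
                    "use generic=True for cold-start prediction")
            logits = self.logits_for(feats, np.asarray(subjects), train_mode=False)
        return softmax(logits, axis=1).data

    def predict_proba(self, dataset, generic: bool = False,
                      batch_size: int = 128) -> np.ndarray:
        """Probabilities for every row of a :class:`StressDataset`."""
        out = []
        for lo in range(0, len(dataset), batch_size):
            sl = slice(lo, lo + batch_size)
            out.append(self.classify(dataset.X[sl], dataset.covariates[sl],
                                     dataset.subjects[sl], generic=generic))
        return np.vstack(out)

    # -- cold start ----------------------------------------------------- #
    def add_subject(self, subject: str) -> None:
        """Register an incoming subject: a fresh personal head initialized
        from the generic head's weights."""
        if subject in self.head_map and self.head_map[subject] in self.heads:
            return
        self.head_map[subject] = subject
        head = Head(self.config.shared_width, self.config.head_hidden, self._rng)
        head.copy_from(self.generic_head)
        self.heads[subject] = head


class ColdStartError(KeyError):
    """Raised when a subject has no personal head; the generic head should
    be used instead."""


def _scatter_rows(pieces: list[tuple[np.ndarray, Tensor]], n: int) -> Tensor:
    """Merge row-subsets back into one (n, k) tensor, differentiably."""
    k = pieces[0][1].data.shape[1]
    data = np.empty((n, k))
    for rows, t in pieces:
        data[rows] = t.data
    req = any(t.requires_grad for _, t in pieces)
    out = Tensor(data, requires_grad=req, parents=tuple(t for _, t in pieces))

    def backward(g):
        for rows, t in pieces:
            if t.requires_grad:
                t._accumulate(g[rows])

    out._backward = backward if req else None
    return out


# ---------------------------------------------------------------------- #
# training loop
# ---------------------------------------------------------------------- #

@dataclass
class TrainConfig:
    """Optimization settings for the integrated loss.

    ``head_warmup_epochs`` freezes the personal heads' weights (their
    output bias stays free, absorbing per-subject base rates) for the
    first epochs; with a branched model this forces the branch layer, not
    the heads, to account for between-subject differences in the stress
    response before the heads personalize.
    """

    epochs: int = 30
    batch_size: int = 32
    lr: float = 1e-3
    branch_lr: float = 2e-2          # selection logits move on a faster clock
    loss: LossWeights = field(default_factory=LossWeights)
    with_generic: bool = True
    tau0: float = 5.0                # branching temperature schedule
    tau_min: float = 0.1
    head_warmup_epochs: int = 0


class Trainer:
    """Resumable mini-batch Adam training of the integrated loss.

    Deterministic given ``seed`` (shuffling and branch-selection noise
    derive from it).  ``run(n)`` advances n epochs and may be called
    repeatedly; ``history`` records the loss terms per epoch.
    """

    def __init__(self, model: StressModel, dataset, cfg: TrainConfig | None = None,
                 seed: int = 0):
        from .branching import BranchedStressModel, TemperatureSchedule  # cycle-free

        self.model = model
        self.dataset = dataset
        self.cfg = cfg = cfg or TrainConfig()
        w = cfg.loss
        if cfg.with_generic and w.lam is None:
            w = LossWeights(w.alpha, w.beta,
                            generic_loss_weight(len(set(dataset.subjects))))
        self.weights = w
        missing = set(model.head_map) - set(dataset.subjects)
        if missing:
            logger.warning("subjects without training examples: %s", sorted(missing))
        self.rng = np.random.default_rng(seed)
        self.epoch = 0
        self.history: list[LossTerms] = []
        self._is_branched = isinstance(model, BranchedStressModel)
        if self._is_branched:
            self.schedule = TemperatureSchedule(cfg.tau0, cfg.tau_min, cfg.epochs)
        self._labels0 = dataset.labels - 1  # to 0-based classes
        self._opt = None

    def _make_optimizer(self, warmup_phase: bool) -> Adam:
        overrides = {}
        if self._is_branched:
            overrides[id(self.model.branch_logits)] = self.cfg.branch_lr
        if warmup_phase:
            for head in self.model.heads.values():
                for p in (head.fc1.W, head.fc1.b, head.fc2.W):
                    overrides[id(p)] = 0.0
        return Adam(self.model.parameters(), lr=self.cfg.lr, lr_overrides=overrides)

    def run(self, n_epochs: int | None = None) -> list[LossTerms]:
        cfg = self.cfg
        stop = cfg.epochs if n_epochs is None else min(cfg.epochs, self.epoch + n_epochs)
        dataset, labels0 = self.dataset, self._labels0
        n = len(dataset)
        while self.epoch < stop:
            epoch = self.epoch
            in_warmup = epoch < cfg.head_warmup_epochs
            if self._opt is None or epoch in (0, cfg.head_warmup_epochs):
                self._opt = self._make_optimizer(in_warmup)
            if self._is_branched:
                self.model.tau = self.schedule.at(epoch)
                self.model.train_rng = self.rng
            order = self.rng.permutation(n)
            ep = np.zeros(3)
            n_batches = 0
            for lo in range(0, n, cfg.batch_size):
                idx = order[lo:lo + cfg.batch_size]
                self.model.zero_grad()
                latent, enc_hs = self.model.encode(dataset.X[idx])
                recon = self.model.decode(enc_hs)
                re = self.model.reconstruction_error(dataset.X[idx], recon)
                feats = self.model.shared_features(latent, dataset.covariates[idx])
                logits = self.model.logits_for(feats, dataset.subjects[idx],
                                               train_mode=True)
                ce_p = cross_entropy(logits, labels0[idx])
                terms_t = LossTerms(re, ce_p)
                if cfg.with_generic:
                    terms_t.ce_generic = cross_entropy(
                        self.model.generic_head(feats), labels0[idx])
                loss = integrated_loss(terms_t, self.weights,
                                       with_generic=cfg.with_generic)
                loss.backward()
                self._opt.step()
                ep += [re.data.item(), ce_p.data.item(),
                       terms_t.ce_generic.data.item() if cfg.with_generic else 0.0]
                n_batches += 1
            self.history.append(LossTerms(*(ep / n_batches)))
            self.epoch += 1
        return self.history

    def eval_personal_ce(self) -> float:
        """Training-set personal-head CE in evaluation mode (hard branch
        routing, no noise) — the model-selection score for restarts."""
        total, n = 0.0, len(self.dataset)
        for lo in range(0, n, 256):
            sl_ = slice(lo, min(lo + 256, n))
            latent, _ = self.model.encode(self.dataset.X[sl_])
            feats = self.model.shared_features(latent, self.dataset.covariates[sl_])
            logits = self.model.logits_for(feats, self.dataset.subjects[sl_],
                                           train_mode=False)
            total += cross_entropy(logits, self._labels0[sl_]).data.item() * (sl_.stop - sl_.start)
        return total / n


def train_model(model: StressModel, dataset, cfg: TrainConfig | None = None,
                seed: int = 0) -> list[LossTerms]:
    """Train to ``cfg.epochs``; returns the per-epoch history of loss terms."""
    return Trainer(model, dataset, cfg, seed).run()


# ---------------------------------------------------------------------- #
# checkpointing
# ---------------------------------------------------------------------- #

CHECKPOINT_VERSION = 1


def save_checkpoint(model: StressModel, path: str) -> None:
    """Write weights plus a versioned JSON manifest.

    ``path`` gets the weight arrays (npz); ``path + '.json'`` records the
    model kind, backbone config, subject-head registry, and branch count,
    enough to rebuild the model and reload the arrays in order.
    """
    import dataclasses
    import json

    from .branching import BranchedStressModel

    params = model.parameters()
    np.savez(path, **{f"p{i}": p.data for i, p in enumerate(params)})
    manifest = {
        "version": CHECKPOINT_VERSION,
        "kind": "branched" if isinstance(model, BranchedStressModel) else "plain",
        "config": dataclasses.asdict(model.config),
        "n_channels": model.n_channels,
        "n_bins": model.n_bins,
        "n_covariates": model.n_covariates,
        "head_map": model.head_map,
        "n_params": len(params),
    }
    if isinstance(model, BranchedStressModel):
        manifest["n_branches"] = model.n_branches
        manifest["subject_order"] = model.subject_order
        manifest["tau"] = model.tau
    with open(str(path) + ".json", "w") as f:
        json.dump(manifest, f, indent=2)


def load_checkpoint(path: str) -> StressModel:
    """Rebuild a model from :func:`save_checkpoint` output."""
    import json

    from .branching import BranchedStressModel

    with open(str(path) + ".json") as f:
        manifest = json.load(f)
    if manifest["version"] != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {manifest['version']}")
    config = BackboneConfig(**manifest["config"])
    subjects = sorted(manifest["head_map"])
    if manifest["kind"] == "branched":
        model = BranchedStressModel(
            manifest["n_channels"], manifest["n_bins"], manifest["n_covariates"],
            manifest["subject_order"], n_branches=manifest["n_branches"],
            config=config)
        model.subject_order = list(manifest["subject_order"])
        model.tau = manifest["tau"]
    else:
        model = StressModel(manifest["n_channels"], manifest["n_bins"],
                            manifest["n_covariates"], subjects, config=config,
                            head_map=manifest["head_map"])
    params = model.parameters()
    if len(params) != manifest["n_params"]:
        raise ValueError("checkpoint does not match reconstructed architecture")
    with np.load(str(path) + (".npz" if not str(path).endswith(".npz") else "")) as data:
        for i, p in enumerate(params):
            arr = data[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.data[...] = arr
    return model
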