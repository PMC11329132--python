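"""Training the ten position models (5 positions x 2 methods) and the
two evaluation regimes: training-data reproduction and leave-one-case-out
cross-validation.

The public surface is the scikit-learn style estimator
:class:`CGANSliceEnhancer` (``fit`` on paired thin/thick cases,
``transform`` thick volumes into thin ones); the module-level functions
``train_position_model``, ``train_all``, ``reproduce_training_eval`` and
``cross_validate`` are thin wrappers over it.

Each of the five position models is trained independently (no weight
sharing), per the pix2pix recipe: alternating single-batch updates of
the conditional PatchGAN discriminator and of the generator, Adam with
learning rate 2e-4 and beta1 = 0.5, generator loss = adversarial BCE +
100 * L1.  Every source of randomness is derived from one seed, so a
fixed seed and config reproduce bit-identical bundles on one platform.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .bundle import ModelBundle, stub_bundle
from .cgan import (ConstantGenerator, DiscriminatorSpec, GeneratorSpec,
                   LossWeights, build_discriminator, build_generator,
                   cgan_losses)
from .enhance import EnhancedVolume, enhance_volume
from .metrics import CaseResult, MetricReport, metric_report, score_slice
from .nn import Adam, bce_with_logits_grad, l1_loss_grad
from .pairing import POSITIONS, make_training_examples
from .phantom import PairedCase
from .volume_io import CTVolume


def derive_seed(base: int, *tokens) -> int:
    """Stable per-stage seed fan-out (crc32 of the token string), < 2^31."""
    tag = ":".join(str(t) for t in tokens)
    return (int(base) * 1000003 + zlib.crc32(tag.encode())) % (2 ** 31)


@dataclass(frozen=True)
class TrainingConfig:
    """Desk-scale training profile; full-scale runs override fields.

    Learning rate, beta1 and the L1 weight are the pix2pix published
    defaults; epochs and network widths are the scaled-down profile
    this package trains with by default.
    """

    epochs: int = 10
    batch_size: int = 1
    lr: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    lambda_l1: float = 100.0
    adv_weight: float = 1.0
    gen_depth: int = 6
    gen_width: int = 32
    disc_blocks: int = 3
    disc_width: int = 32
    k: int = 3
    shuffle: bool = True
    seed: int = 0


def train_position_model(examples, config: TrainingConfig
                         ) -> tuple[object, list[dict]]:
    """Train one position model on its examples; returns (generator, history).

    ``history`` has one record per epoch with the mean generator and
    discriminator losses.
    """
    if not examples:
        raise ValueError("empty example list")
    position = examples[0].position
    method = examples[0].method
    if any(ex.position != position or ex.method != method for ex in examples):
        raise ValueError("all examples must share one position and one method")

    h, w = examples[0].input.shape
    gen = build_generator(
        GeneratorSpec(in_channels=1, depth=config.gen_depth,
                      base_width=config.gen_width,
                      seed=derive_seed(config.seed, "gen", method, position.value)),
        image_size=h)
    disc = build_discriminator(
        DiscriminatorSpec(in_channels=2, n_strided=config.disc_blocks,
                          base_width=config.disc_width,
                          seed=derive_seed(config.seed, "disc", method, position.value)))
    weights = LossWeights(adversarial=config.adv_weight, l1=config.lambda_l1)
    g_opt = Adam(gen, lr=config.lr, beta1=config.beta1, beta2=config.beta2)
    d_opt = Adam(disc, lr=config.lr, beta1=config.beta1, beta2=config.beta2)
    order_rng = np.random.default_rng(
        derive_seed(config.seed, "order", method, position.value))

    xs = np.stack([ex.input for ex in examples])[:, None].astype(np.float32)
    ts = np.stack([ex.target for ex in examples])[:, None].astype(np.float32)
    m = len(examples)

    history = []
    for _ in range(config.epochs):
        order = order_rng.permutation(m) if config.shuffle else np.arange(m)
        g_losses, d_losses = [], []
        for start in range(0, m, config.batch_size):
            idx = order[start:start + config.batch_size]
            x, t = xs[idx], ts[idx]
            fake = gen.forward(x)

            # discriminator update on (x, y) vs (x, G(x)); G(x) detached
            disc.zero_grad()
            z_real = disc.forward(x, t)
            disc.backward(bce_with_logits_grad(z_real, weights.real_label) * 0.5)
            z_fake = disc.forward(x, fake)
            disc.backward(bce_with_logits_grad(z_fake, weights.fake_label) * 0.5)
            d_opt.step()

            # generator update: adversarial (non-saturating) + lambda * L1
            gen.zero_grad()
            disc.zero_grad()
            z_fake2 = disc.forward(x, fake)
            g_adv = disc.backward(
                bce_with_logits_grad(z_fake2, weights.real_label)
                * weights.adversarial)
            g_l1 = l1_loss_grad(fake, t) * weights.l1
            gen.backward(g_adv + g_l1)
            g_opt.step()

            g_loss, d_loss = cgan_losses(z_real, z_fake2, t, fake, weights)
            g_losses.append(g_loss)
            d_losses.append(d_loss)
        history.append({"g_loss": float(np.mean(g_losses)),
                        "d_loss": float(np.mean(d_losses))})
    return gen, history


class CGANSliceEnhancer(BaseEstimator, TransformerMixin):
    """Conditional-GAN slice-thickness reducer/interpolator.

    Fits five position-specific U-Net generators (2P, 1P, C, 1N, 2N) on
    paired thin/thick cases and transforms thick volumes into thin-slice
    volumes.  ``method=1`` trains on raw thin-slice targets; ``method=2``
    trains on thick-to-thin difference images and adds the predicted
    residual back to the input at inference.

    Parameters mirror :class:`TrainingConfig`; fitted attributes are
    ``bundle_`` (the five trained generators), ``history_`` (per-position
    loss curves) and ``case_ids_``.
    """

    def __init__(self, method: int = 2, epochs: int = 10, batch_size: int = 1,
                 lr: float = 2e-4, beta1: float = 0.5, beta2: float = 0.999,
                 lambda_l1: float = 100.0, adv_weight: float = 1.0,
                 gen_depth: int = 6, gen_width: int = 32,
                 disc_blocks: int = 3, disc_width: int = 32,
                 k: int = 3, shuffle: bool = True, overlap: str = "mean",
                 random_state: int = 0):
        self.method = method
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.lambda_l1 = lambda_l1
        self.adv_weight = adv_weight
        self.gen_depth = gen_depth
        self.gen_width = gen_width
        self.disc_blocks = disc_blocks
        self.disc_width = disc_width
        self.k = k
        self.shuffle = shuffle
        self.overlap = overlap
        self.random_state = random_state

    def _config(self) -> TrainingConfig:
        return TrainingConfig(
            epochs=self.epochs, batch_size=self.batch_size, lr=self.lr,
            beta1=self.beta1, beta2=self.beta2, lambda_l1=self.lambda_l1,
            adv_weight=self.adv_weight, gen_depth=self.gen_depth,
            gen_width=self.gen_width, disc_blocks=self.disc_blocks,
            disc_width=self.disc_width, k=self.k, shuffle=self.shuffle,
            seed=self.random_state)

    def fit(self, X, y=None):
        """Fit the five position models on a list of :class:`PairedCase`."""
        cases = list(X)
        if not cases:
            raise ValueError("need at least one paired case")
        if self.method not in (1, 2):
            raise ValueError(f"method must be 1 or 2, got {self.method}")
        config = self._config()
        generators, history, n_examples = {}, {}, {}
        for position in POSITIONS:
            examples = []
            for case in cases:
                examples.extend(make_training_examples(case, position, self.method))
            gen, hist = train_position_model(examples, config)
            generators[position] = gen
            history[position.value] = hist
            n_examples[position.value] = len(examples)
        self.case_ids_ = [c.case_id for c in cases]
        self.history_ = history
        self.bundle_ = ModelBundle(
            method=self.method, generators=generators, k=self.k,
            provenance={"case_ids": self.case_ids_,
                        "config": asdict(config),
                        "n_examples": n_examples})
        return self

    def transform(self, X) -> EnhancedVolume | list[EnhancedVolume]:
        """Enhance a thick :class:`CTVolume` (or a list of them)."""
        if not hasattr(self, "bundle_"):
            raise RuntimeError("estimator is not fitted")
        if isinstance(X, CTVolume):
            return enhance_volume(self.bundle_, X, overlap=self.overlap)
        return [enhance_volume(self.bundle_, v, overlap=self.overlap) for v in X]

    def score(self, X, y=None) -> float:
        """Mean pooled PSNR (dB) over the covered slices of the given cases."""
        report = reproduce_training_eval(self.bundle_, list(X),
                                         require_training_cases=False,
                                         overlap=self.overlap)
        return report.grand_means(self.method)["pooled"]["psnr"]


# ---------------------------------------------------------------------------
# Evaluation regimes
# ---------------------------------------------------------------------------

def evaluate_case(bundle: ModelBundle, case: PairedCase,
                  overlap: str = "mean") -> CaseResult:
    """Enhance a case's thick volume and score it against its thin truth
    slice-by-slice over the covered thin indices."""
    enhanced = enhance_volume(bundle, case.thick, overlap=overlap)
    lo = enhanced.index_offset
    pred = enhanced.volume.voxels
    truth = case.thin.voxels[lo:lo + pred.shape[0]]
    triples = [score_slice(p, t) for p, t in zip(pred, truth)]
    return CaseResult(case_id=case.case_id, triples=triples)


def copy_baseline_case(case: PairedCase, overlap: str = "mean") -> CaseResult:
    """Naive baseline: every thin position predicted as a copy of its
    thick input slice (zero-residual stub), assembled the same way."""
    baseline = stub_bundle(ConstantGenerator(0.0), method=2, k=case.mapping.k)
    return evaluate_case(baseline, case, overlap=overlap)


def reproduce_training_eval(bundle: ModelBundle, cases: list[PairedCase],
                            require_training_cases: bool = True,
                            overlap: str = "mean") -> MetricReport:
    """Score the bundle on the cases it was trained on (reproduction check)."""
    if require_training_cases and bundle.training_case_ids:
        trained = set(bundle.training_case_ids)
        unknown = [c.case_id for c in cases if c.case_id not in trained]
        if unknown:
            raise ValueError(f"cases not in the bundle's training set: {unknown}")
    results = [evaluate_case(bundle, c, overlap=overlap) for c in cases]
    return metric_report({bundle.method: results})


def train_all(cases: list[PairedCase], method: int,
              config: TrainingConfig = TrainingConfig()) -> ModelBundle:
    """Train the five position models of one method over the cases."""
    est = CGANSliceEnhancer(method=method, **{f: getattr(config, f)
                                              for f in ("epochs", "batch_size", "lr",
                                                        "beta1", "beta2", "lambda_l1",
                                                        "adv_weight", "gen_depth",
                                                        "gen_width", "disc_blocks",
                                                        "disc_width", "k", "shuffle")},
                            random_state=config.seed)
    return est.fit(cases).bundle_


@dataclass
class FoldResult:
    """One leave-one-case-out fold: held-out report plus bookkeeping."""

    fold_index: int
    test_case_id: str
    train_case_ids: list[str]
    report: MetricReport
    baseline: CaseResult
    bundle_checksum: str


def cross_validate(cases: list[PairedCase], config: TrainingConfig,
                   method: int, folds: list[int] | None = None,
                   overlap: str = "mean") -> list[FoldResult]:
    """Leave-one-case-out cross-validation (optionally a subset of folds).

    Fold i holds out ``cases[i]``, trains a fresh bundle on the rest,
    and evaluates on the held-out case.
    """
    if len(cases) < 2:
        raise ValueError("cross-validation needs at least 2 cases")
    fold_indices = list(range(len(cases))) if folds is None else list(folds)
    results = []
    for i in fold_indices:
        if not 0 <= i < len(cases):
            raise IndexError(f"fold index {i} out of range")
        test_case = cases[i]
        train_cases = [c for j, c in enumerate(cases) if j != i]
        fold_config = TrainingConfig(**{**asdict(config),
                                        "seed": derive_seed(config.seed, "fold", i)})
        bundle = train_all(train_cases, method, fold_config)
        report = metric_report({method: [evaluate_case(bundle, test_case,
                                                       overlap=overlap)]})
        results.append(FoldResult(
            fold_index=i,
            test_case_id=test_case.case_id,
            train_case_ids=[c.case_id for c in train_cases],
            report=report,
            baseline=copy_baseline_case(test_case, overlap=overlap),
            bundle_checksum=bundle.checksum(),
        ))
    return results
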