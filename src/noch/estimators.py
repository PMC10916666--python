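"""scikit-learn-style estimators wrapping the translation and evaluation
machinery, so the pieces compose with sklearn pipelines and model selection.

``NOCHTranslator`` is the headline transformer: ``fit`` trains the
contrastive translation network on two image domains, ``transform`` renders
virtual H&E from label-free inputs. ``StainDeconvolver``,
``NucleiSegmenter`` and ``GridClassifier`` wrap the evaluation stages with
the same conventions (constructor params, ``get_params``/``set_params``,
fitted attributes with trailing underscores).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .adversarial import LossWeights
from .classification import (DEFAULT_CELL_UM, ReferenceCNNClassifier,
                             UniformClassifier, accuracy_map, classify_grid)
from .generator import ResnetGenerator, translate
from .histomorphometry import (DEFAULT_STAIN_MATRIX, SegmentationParams,
                               segment_nuclei, stain_deconvolve,
                               summarize_morphometry)
from .imagedata import MultichannelImage, StainedImage
from .training import TrainConfig, Trainer, prepare_input


class NOCHTranslator(BaseEstimator, TransformerMixin):
    """Unpaired contrastive image-to-image translator (label-free -> H&E).

    Parameters mirror the training configuration; ``fit(X, y)`` takes the
    label-free domain as ``X`` (list of MultichannelImage) and the stained
    domain as ``y`` (list of StainedImage). After fitting,
    ``transform(X)`` returns virtual H&E StainedImages.

    Attributes
    ----------
    generator_ : the trained translation network
    projector_ : the trained per-layer feature projectors
    record_ : RunRecord with per-iteration loss components and the
        selected checkpoint
    """

    def __init__(self, iterations=2000, tile_size=64, learning_rate=2e-4,
                 adam_beta1=0.5, adam_beta2=0.999, split_mode="paired",
                 mode="self_contrastive", n_locations=64, tau=0.07,
                 lambda_gan=1.0, lambda_X=1.0, lambda_Y=1.0,
                 gen_base_width=16, n_res_blocks=2, disc_base_width=16,
                 disc_n_layers=2, projector_dim=64, projector_hidden=64,
                 augment=True, validation_every=250, gan_variant="logistic",
                 nce_reduction="mean", bank_capacity=1024, momentum_m=0.999,
                 dtype="float32", seed=0):
        self.iterations = iterations
        self.tile_size = tile_size
        self.learning_rate = learning_rate
        self.adam_beta1 = adam_beta1
        self.adam_beta2 = adam_beta2
        self.split_mode = split_mode
        self.mode = mode
        self.n_locations = n_locations
        self.tau = tau
        self.lambda_gan = lambda_gan
        self.lambda_X = lambda_X
        self.lambda_Y = lambda_Y
        self.gen_base_width = gen_base_width
        self.n_res_blocks = n_res_blocks
        self.disc_base_width = disc_base_width
        self.disc_n_layers = disc_n_layers
        self.projector_dim = projector_dim
        self.projector_hidden = projector_hidden
        self.augment = augment
        self.validation_every = validation_every
        self.gan_variant = gan_variant
        self.nce_reduction = nce_reduction
        self.bank_capacity = bank_capacity
        self.momentum_m = momentum_m
        self.dtype = dtype
        self.seed = seed

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate, adam_beta1=self.adam_beta1,
            adam_beta2=self.adam_beta2, iterations=self.iterations,
            tile_size=self.tile_size, split_mode=self.split_mode,
            mode=self.mode, augment=self.augment,
            validation_every=self.validation_every,
            n_locations=self.n_locations, tau=self.tau,
            gan_variant=self.gan_variant,
            nce_reduction=self.nce_reduction,
            weights=LossWeights(self.lambda_gan, self.lambda_X, self.lambda_Y),
            gen_base_width=self.gen_base_width,
            n_res_blocks=self.n_res_blocks,
            disc_base_width=self.disc_base_width,
            disc_n_layers=self.disc_n_layers,
            projector_dim=self.projector_dim,
            projector_hidden=self.projector_hidden,
            bank_capacity=self.bank_capacity, momentum_m=self.momentum_m,
            dtype=self.dtype, seed=self.seed)

    def fit(self, X, y):
        if not X or not y:
            raise ValueError("both image domains must be non-empty")
        trainer = Trainer(list(X), list(y), self._train_config())
        self.record_ = trainer.run()
        self.generator_ = trainer.G
        self.projector_ = trainer.projector
        return self

    def transform(self, X) -> list[StainedImage]:
        if not hasattr(self, "generator_"):
            raise RuntimeError("NOCHTranslator is not fitted")
        return [self.translate_one(x) for x in X]

    def translate_one(self, x: MultichannelImage) -> StainedImage:
        return translate(prepare_input(x), self.generator_)


class StainDeconvolver(BaseEstimator, TransformerMixin):
    """Optical-density H&E stain unmixing as a transformer.

    Stateless apart from the stain matrix; ``fit`` validates and stores it,
    ``transform`` maps StainedImages to DeconvolutionResults.
    """

    def __init__(self, stain_matrix=None):
        self.stain_matrix = stain_matrix

    def fit(self, X=None, y=None):
        from .histomorphometry import validate_stain_matrix
        M = DEFAULT_STAIN_MATRIX if self.stain_matrix is None \
            else np.asarray(self.stain_matrix)
        self.stain_matrix_ = validate_stain_matrix(M)
        return self

    def transform(self, X):
        if not hasattr(self, "stain_matrix_"):
            self.fit()
        return [stain_deconvolve(img, self.stain_matrix_) for img in X]


class NucleiSegmenter(BaseEstimator):
    """Nuclear segmentation with the classical fallback or a plugin detector.

    ``predict(imgs)`` returns one list of NucleusRecord per image;
    ``summarize(img)`` returns the MorphometrySummary used by the
    distribution comparisons.
    """

    def __init__(self, method="classical_fallback", smooth_sigma_um=0.5,
                 min_area_um2=8.0, max_area_um2=400.0,
                 min_peak_distance_um=3.0):
        self.method = method
        self.smooth_sigma_um = smooth_sigma_um
        self.min_area_um2 = min_area_um2
        self.max_area_um2 = max_area_um2
        self.min_peak_distance_um = min_peak_distance_um

    def _params(self) -> SegmentationParams:
        return SegmentationParams(
            smooth_sigma_um=self.smooth_sigma_um,
            min_area_um2=self.min_area_um2,
            max_area_um2=self.max_area_um2,
            min_peak_distance_um=self.min_peak_distance_um)

    def fit(self, X=None, y=None):
        return self

    def predict(self, X):
        return [segment_nuclei(img, self.method, self._params()) for img in X]

    def summarize(self, img: StainedImage):
        nuclei = segment_nuclei(img, self.method, self._params())
        return summarize_morphometry(nuclei, img.pixel_size_um)


class GridClassifier(BaseEstimator):
    """Grid-wise stage classifier over a pluggable tile model.

    ``model`` is any callable tile -> probability vector; when None, ``fit``
    trains the reference CNN on (tiles, labels).
    """

    def __init__(self, model=None, cell_um=DEFAULT_CELL_UM, input_px=32,
                 width=8, epochs=30, seed=0):
        self.model = model
        self.cell_um = cell_um
        self.input_px = input_px
        self.width = width
        self.epochs = epochs
        self.seed = seed

    def fit(self, tiles=None, labels=None):
        if self.model is not None:
            self.model_ = self.model
        elif tiles is not None and labels is not None:
            self.model_ = ReferenceCNNClassifier(
                input_px=self.input_px, width=self.width,
                epochs=self.epochs, seed=self.seed).fit(tiles, labels)
        else:
            self.model_ = UniformClassifier()
        return self

    def predict_proba_map(self, img: StainedImage):
        if not hasattr(self, "model_"):
            raise RuntimeError("GridClassifier is not fitted")
        return classify_grid(img, self.model_, self.cell_um)

    def score_map(self, img: StainedImage, truth):
        return accuracy_map(self.predict_proba_map(img), truth)
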