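"""The combined CNN-VAE classifier and its single-stage ablations.

Fitting is strictly sequential: the CNN (with its own dense head) is
trained on the input images, its activated pre-pooling convolutional
features (900-dimensional at the defaults) are extracted with the CNN
frozen, and the VAE classifier is pretrained and fine-tuned on those
features.  At prediction time the CNN head is discarded: the VAE head is
the sole classifier.

All randomness derives from the pipeline's master seed (CNN seed = master
+ 1, VAE seed = master + 2).  Optional input normalization z-scores pixels
with statistics computed on the training set only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import h5py
import numpy as np

from . import cnn as _cnn
from . import vae as _vae
from .representation import ImageSet, RepresentationConfig, build_inputs
from .synth import TrialSet

__all__ = [
    "PipelineConfig",
    "Pipeline",
    "CnnClassifier",
    "VaeClassifier",
    "downsample_image",
    "save_pipeline",
    "load_pipeline",
]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    representation: RepresentationConfig = field(default_factory=RepresentationConfig)
    cnn: _cnn.CnnConfig = field(default_factory=_cnn.CnnConfig)
    vae: _vae.VaeConfig = field(default_factory=_vae.VaeConfig)
    seed: int = 0
    normalize: bool = True

    def __post_init__(self) -> None:
        nt = self.representation.n_frames
        feat = self.cnn.feature_dim(nt)
        if feat != self.vae.input_dim:
            raise ValueError(
                "stage dimension mismatch: CNN feature dim "
                f"n_filters*(Nt - kernel_width + 1) = {self.cnn.n_filters}*"
                f"({nt} - {self.cnn.kernel_width} + 1) = {feat} but "
                f"VaeConfig.input_dim = {self.vae.input_dim}"
            )


def _normalizer(images: np.ndarray) -> tuple[float, float]:
    mean = float(images.mean())
    sd = float(images.std())
    return mean, sd if sd > 0 else 1.0


class Pipeline:
    """Train/predict facade over the CNN feature extractor + VAE classifier."""

    def __init__(self, config: PipelineConfig) -> None:
        self.config = config
        self.cnn_model: _cnn.CnnModel | None = None
        self.vae_model: _vae.VaeModel | None = None
        self.cnn_history: _cnn.TrainingHistory | None = None
        self.vae_history: _cnn.TrainingHistory | None = None
        self.norm_stats: tuple[float, float] | None = None

    # ------------------------------------------------------------------
    def _to_images(self, data) -> ImageSet:
        if isinstance(data, TrialSet):
            return build_inputs(data, self.config.representation)
        if isinstance(data, ImageSet):
            return data
        raise TypeError(f"expected TrialSet or ImageSet, got {type(data).__name__}")

    def _apply_norm(self, images: ImageSet) -> ImageSet:
        if self.norm_stats is None:
            return images
        mean, sd = self.norm_stats
        return ImageSet(
            images=(images.images - mean) / sd,
            labels=images.labels,
            channel_order=images.channel_order,
            band_layout=images.band_layout,
        )

    def fit(self, data) -> "Pipeline":
        images = self._to_images(data)
        if self.config.normalize:
            self.norm_stats = _normalizer(images.images)
        images = self._apply_norm(images)
        nh, nt = images.images.shape[1:]
        cnn_cfg = replace(self.config.cnn, seed=self.config.seed + 1)
        self.cnn_model = _cnn.init_cnn(cnn_cfg, (nh, nt))
        self.cnn_model, self.cnn_history = _cnn.train_cnn(self.cnn_model, images)
        feats = _cnn.extract_features(self.cnn_model, images)
        vae_cfg = replace(self.config.vae, seed=self.config.seed + 2)
        self.vae_model = _vae.init_vae(vae_cfg)
        _vae.pretrain_layerwise(self.vae_model, feats)
        _, self.vae_history = _vae.finetune(self.vae_model, feats, images.labels)
        return self

    def predict(self, data) -> tuple[np.ndarray, np.ndarray]:
        """(integer labels, probability pairs) for trials or images."""
        if self.cnn_model is None or self.vae_model is None:
            raise RuntimeError("pipeline is not fitted")
        images = self._apply_norm(self._to_images(data))
        feats = _cnn.extract_features(self.cnn_model, images)
        return _vae.predict(self.vae_model, feats)

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        save_pipeline(self, path)

    @classmethod
    def load(cls, path) -> "Pipeline":
        return load_pipeline(path)


class CnnClassifier:
    """Ablation: the CNN alone, classifying with its own dense head."""

    def __init__(self, config: PipelineConfig) -> None:
        self.config = config
        self.model: _cnn.CnnModel | None = None
        self.norm_stats: tuple[float, float] | None = None

    def fit(self, images: ImageSet) -> "CnnClassifier":
        if self.config.normalize:
            self.norm_stats = _normalizer(images.images)
            images = _norm_images(images, self.norm_stats)
        nh, nt = images.images.shape[1:]
        cfg = replace(self.config.cnn, seed=self.config.seed + 1)
        self.model = _cnn.init_cnn(cfg, (nh, nt))
        self.model, _ = _cnn.train_cnn(self.model, images)
        return self

    def predict(self, images: ImageSet) -> tuple[np.ndarray, np.ndarray]:
        if self.model is None:
            raise RuntimeError("not fitted")
        if self.norm_stats is not None:
            images = _norm_images(images, self.norm_stats)
        probs = _cnn.cnn_forward(self.model, images)
        return np.argmax(np.atleast_2d(probs), axis=1), np.atleast_2d(probs)


def downsample_image(images: np.ndarray, grid: tuple[int, int] = (30, 30)) -> np.ndarray:
    """Adaptive average-pooling of (n, Nh, Nt) images to a fixed grid.

    Rows and columns are split into nearly equal contiguous blocks and
    averaged, producing grid[0]*grid[1] (=900 by default) values per image
    regardless of Nh -- the standalone-VAE input transformation.
    """
    images = np.asarray(images)
    n, nh, nt = images.shape
    row_chunks = np.array_split(np.arange(nh), grid[0])
    col_chunks = np.array_split(np.arange(nt), grid[1])
    out = np.empty((n, grid[0], grid[1]), dtype=images.dtype)
    for i, rc in enumerate(row_chunks):
        band = images[:, rc, :].mean(axis=1)
        for j, cc in enumerate(col_chunks):
            out[:, i, j] = band[:, cc].mean(axis=1)
    return out.reshape(n, -1)


class VaeClassifier:
    """Ablation: the VAE alone on down-sampled 900-value input images."""

    def __init__(self, config: PipelineConfig) -> None:
        self.config = config
        self.model: _vae.VaeModel | None = None
        self.norm_stats: tuple[float, float] | None = None

    def _features(self, images: ImageSet) -> np.ndarray:
        if self.norm_stats is not None:
            images = _norm_images(images, self.norm_stats)
        return downsample_image(images.images)

    def fit(self, images: ImageSet) -> "VaeClassifier":
        if self.config.normalize:
            self.norm_stats = _normalizer(images.images)
        feats = self._features(images)
        cfg = replace(self.config.vae, seed=self.config.seed + 2, input_dim=feats.shape[1])
        self.model = _vae.init_vae(cfg)
        _vae.pretrain_layerwise(self.model, feats)
        _vae.finetune(self.model, feats, images.labels)
        return self

    def predict(self, images: ImageSet) -> tuple[np.ndarray, np.ndarray]:
        if self.model is None:
            raise RuntimeError("not fitted")
        return _vae.predict(self.model, self._features(images))


def _norm_images(images: ImageSet, stats: tuple[float, float]) -> ImageSet:
    mean, sd = stats
    return ImageSet(
        images=(images.images - mean) / sd,
        labels=images.labels,
        channel_order=images.channel_order,
        band_layout=images.band_layout,
    )


# ----------------------------------------------------------------------
# persistence


def _write_dense(grp: h5py.Group, name: str, layer) -> None:
    g = grp.create_group(name)
    g.create_dataset("W", data=layer.W)
    g.create_dataset("b", data=layer.b)


def _read_dense(grp: h5py.Group, name: str):
    from ._nn import Dense

    g = grp[name]
    layer = Dense(g["W"].shape[1], g["W"].shape[0])
    layer.W = g["W"][()]
    layer.b = g["b"][()]
    return layer


def save_pipeline(p: Pipeline, path) -> None:
    if p.cnn_model is None or p.vae_model is None:
        raise RuntimeError("cannot save an unfitted pipeline")
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["config"] = json.dumps(_config_to_dict(p.config))
        f.attrs["input_shape"] = p.cnn_model.input_shape
        if p.norm_stats is not None:
            f.attrs["norm_mean"], f.attrs["norm_sd"] = p.norm_stats
        g = f.create_group("cnn")
        g.create_dataset("W", data=p.cnn_model.W)
        g.create_dataset("b", data=p.cnn_model.b)
        _write_dense(g, "head", p.cnn_model.head)
        g = f.create_group("vae")
        core = p.vae_model.core
        for i, layer in enumerate(core.enc_hidden):
            _write_dense(g, f"enc{i}", layer)
        _write_dense(g, "enc_mu", core.enc_mu)
        _write_dense(g, "enc_s", core.enc_s)
        for i, layer in enumerate(core.dec_hidden):
            _write_dense(g, f"dec{i}", layer)
        _write_dense(g, "dec_mu", core.dec_mu)
        g.create_dataset("dec_logvar", data=core.dec_logvar)
        _write_dense(g, "head", p.vae_model.head)


def load_pipeline(path) -> Pipeline:
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ValueError(f"cannot read pipeline file {path}: {exc}") from exc
    with f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported pipeline schema version {version!r} "
                f"(expected {SCHEMA_VERSION})"
            )
        cfg = _config_from_dict(json.loads(f.attrs["config"]))
        p = Pipeline(cfg)
        input_shape = tuple(int(v) for v in f.attrs["input_shape"])
        if "norm_mean" in f.attrs:
            p.norm_stats = (float(f.attrs["norm_mean"]), float(f.attrs["norm_sd"]))
        cnn_cfg = replace(cfg.cnn, seed=cfg.seed + 1)
        model = _cnn.init_cnn(cnn_cfg, input_shape)
        model.W = f["cnn/W"][()]
        model.b = f["cnn/b"][()]
        model.head = _read_dense(f["cnn"], "head")
        p.cnn_model = model
        vae_cfg = replace(cfg.vae, seed=cfg.seed + 2)
        vm = _vae.init_vae(vae_cfg)
        core = vm.core
        g = f["vae"]
        core.enc_hidden = [_read_dense(g, f"enc{i}") for i in range(len(core.enc_hidden))]
        core.enc_mu = _read_dense(g, "enc_mu")
        core.enc_s = _read_dense(g, "enc_s")
        core.dec_hidden = [_read_dense(g, f"dec{i}") for i in range(len(core.dec_hidden))]
        core.dec_mu = _read_dense(g, "dec_mu")
        core.dec_logvar = g["dec_logvar"][()]
        vm.head = _read_dense(g, "head")
        p.vae_model = vm
    return p


def _config_to_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["representation"]["bands"] = [asdict(b) for b in cfg.representation.bands]
    return d


def _config_from_dict(d: dict) -> PipelineConfig:
    from .representation import BandSpec, StftParams

    rep = d["representation"]
    rep_cfg = RepresentationConfig(
        stft=StftParams(**rep["stft"]),
        bands=tuple(BandSpec(**b) for b in rep["bands"]),
        epoch_start_s=rep["epoch_start_s"],
        epoch_len_s=rep["epoch_len_s"],
    )
    cnn_cfg = _cnn.CnnConfig(**d["cnn"])
    vae_cfg = _vae.VaeConfig(hidden_dims=tuple(d["vae"].pop("hidden_dims")), **d["vae"])
    return PipelineConfig(
        representation=rep_cfg,
        cnn=cnn_cfg,
        vae=vae_cfg,
        seed=d["seed"],
        normalize=d["normalize"],
    )
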