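"""End-to-end orchestration and command-line interface.

Thin layer over the library: simulate phantoms, train the translator,
translate held-out images, evaluate morphometry and stain composition, and
classify stage maps. Every artifact directory receives a ``run.json`` with
the configuration hash and master seed so outputs are attributable to one
run.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import typer
import yaml

from .classification import (UniformClassifier, ReferenceCNNClassifier,
                             accuracy_map, classify_grid, save_probability_map)
from .estimators import NOCHTranslator, NucleiSegmenter
from .histomorphometry import compare_distributions, stain_deconvolve
from .imagedata import read_image, read_manifest, write_image
from .synthdata import PhantomParams, generate_dataset
from .training import split_dataset

app = typer.Typer(add_completion=False, help="Nonlinear-optical computational "
                  "histology: virtual H&E translation and evaluation.")


@dataclass
class RunConfig:
    subcommand: str
    paths: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stamp(out_dir: Path, cfg: RunConfig, extra: dict | None = None) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"config": asdict(cfg), "config_hash": cfg.config_hash(),
               "seed": cfg.seed}
    if extra:
        payload.update(extra)
    with open(out_dir / "run.json", "w") as fh:
        json.dump(payload, fh, indent=1, default=str)


def _load_yaml(path) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _load_dataset(manifest_path: Path):
    entries = read_manifest(manifest_path)
    root = manifest_path.parent
    xs, ys, pairs = [], [], []
    for e in entries:
        if e["domain"] == "X":
            img = read_image(root / e["path"], "multichannel",
                             modalities=e.get("modalities"),
                             pixel_size_um=e.get("pixel_size_um"))
            xs.append((e, img))
            if e.get("pair"):
                pairs.append((e, img, read_image(
                    root / e["pair"], "stained",
                    pixel_size_um=e.get("pixel_size_um"))))
        else:
            ys.append((e, read_image(root / e["path"], "stained",
                                     pixel_size_um=e.get("pixel_size_um"))))
    return xs, ys, pairs


@app.command()
def simulate(out: Path = typer.Option(..., help="output directory"),
             n: int = typer.Option(10, help="number of phantom pairs"),
             config: Path = typer.Option(None, help="phantom YAML config"),
             image_size: int = 512, seed: int = 0,
             misregister: bool = True):
    """Generate a paired phantom dataset with ground-truth sidecars."""
    opts = _load_yaml(config)
    opts.setdefault("image_size", image_size)
    template = PhantomParams(**opts)
    cfg = RunConfig("simulate", {"out": str(out)},
                    {"n": n, **asdict(template)}, seed)
    manifest, entries = generate_dataset(n, out, template=template, seed=seed,
                                         misregister=misregister)
    _stamp(out, cfg, {"manifest": str(manifest), "n_entries": len(entries)})
    typer.echo(f"wrote {len(entries)} images + manifest to {out}")


@app.command()
def train(data: Path = typer.Option(..., help="manifest.json from simulate "
                                    "or a hand-written dataset manifest"),
          out: Path = typer.Option(...),
          config: Path = typer.Option(None, help="training YAML config"),
          iterations: int = 500, tile_size: int = 64,
          ratio_test: int = 1, ratio_train: int = 4, seed: int = 0):
    """Train the contrastive translation network; writes checkpoint + logs."""
    opts = _load_yaml(config)
    opts.setdefault("iterations", iterations)
    opts.setdefault("tile_size", tile_size)
    opts.setdefault("seed", seed)
    cfg = RunConfig("train", {"data": str(data), "out": str(out)}, opts, seed)
    xs, ys, pairs = _load_dataset(Path(data))
    if pairs and len(pairs) == len(xs):
        train_pairs, test_pairs, policy = split_dataset(
            pairs, (ratio_test, ratio_train), seed)
        x_imgs = [p[1] for p in train_pairs]
        y_imgs = [p[2] for p in train_pairs]
        split_info = {"train": [p[0]["path"] for p in train_pairs],
                      "test": [p[0]["path"] for p in test_pairs],
                      "policy": policy}
        opts.setdefault("split_mode", "paired")
    else:
        x_imgs = [x[1] for x in xs]
        y_imgs = [y[1] for y in ys]
        split_info = {"train": [x[0]["path"] for x in xs], "test": [],
                      "policy": "unpaired: no held-out pairs"}
        opts.setdefault("split_mode", "unpaired")
    translator = NOCHTranslator(**opts)
    translator.fit(x_imgs, y_imgs)
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    from .training import save_checkpoint
    save_checkpoint(out / "generator.npz", translator.generator_,
                    translator._train_config())
    translator.record_.train_ids = split_info["train"]
    translator.record_.test_ids = split_info["test"]
    translator.record_.to_jsonl(out / "losses.jsonl")
    _stamp(out, cfg, {"split": split_info,
                      "selected_checkpoint":
                          translator.record_.selected_checkpoint})
    typer.echo(f"trained {opts['iterations']} iterations; "
               f"checkpoint at {out/'generator.npz'}")


@app.command()
def translate(image: Path = typer.Option(...),
              checkpoint: Path = typer.Option(...),
              out: Path = typer.Option(...),
              pixel_size: float = typer.Option(None),
              seed: int = 0):
    """Translate a label-free image to virtual H&E with a trained model."""
    from .generator import translate as translate_fn
    from .training import load_checkpoint, prepare_input
    cfg = RunConfig("translate", {"image": str(image),
                                  "checkpoint": str(checkpoint),
                                  "out": str(out)}, {}, seed)
    model = load_checkpoint(checkpoint)
    img = read_image(image, "multichannel", pixel_size_um=pixel_size)
    virt = translate_fn(prepare_input(img), model)
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    write_image(out / (Path(image).stem + "_noch.png"), virt)
    _stamp(out, cfg)
    typer.echo(f"wrote {out / (Path(image).stem + '_noch.png')}")


@app.command()
def evaluate(image: Path = typer.Option(..., help="stained image (real or "
                                        "virtual H&E)"),
             out: Path = typer.Option(...),
             pixel_size: float = typer.Option(0.65, help="µm per pixel"),
             reference: Path = typer.Option(None, help="optional second "
                                            "stained image to compare against"),
             seed: int = 0):
    """Stain deconvolution + nuclear morphometry report for a stained image."""
    import pandas as pd
    cfg = RunConfig("evaluate", {"image": str(image), "out": str(out)},
                    {"pixel_size": pixel_size}, seed)
    img = read_image(image, "stained", pixel_size_um=pixel_size)
    seg = NucleiSegmenter()
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    dec = stain_deconvolve(img)
    summary = seg.summarize(img)
    nuclei = seg.predict([img])[0]
    pd.DataFrame([{"id": n.label, "x_um": n.x_um, "y_um": n.y_um,
                   "area_um2": n.area_um2} for n in nuclei]).to_csv(
        out / "nuclei.csv", index=False)
    report = {
        "I_hemat": dec.I_hemat, "I_eosin": dec.I_eosin,
        "prop_hematoxylin": dec.prop_hematoxylin,
        "n_nuclei": summary.n_nuclei,
        "area_um2_mean_ci95": summary.area_mean_ci,
        "nn_distance_um_mean_ci95": summary.nn_mean_ci,
    }
    if reference is not None:
        ref = read_image(reference, "stained", pixel_size_um=pixel_size)
        report["comparison"] = compare_distributions(
            summary, seg.summarize(ref))
    with open(out / "morphometry.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    _stamp(out, cfg)
    typer.echo(json.dumps(report, indent=1, default=str))


@app.command()
def classify(image: Path = typer.Option(...),
             out: Path = typer.Option(...),
             pixel_size: float = typer.Option(0.65),
             cell_um: float = typer.Option(334.0),
             truth: str = typer.Option(None, help="ground-truth stage label"),
             seed: int = 0):
    """Grid-wise stage probability map (uniform stub model unless a trained
    classifier checkpoint is wired in programmatically)."""
    cfg = RunConfig("classify", {"image": str(image), "out": str(out)},
                    {"cell_um": cell_um}, seed)
    img = read_image(image, "stained", pixel_size_um=pixel_size)
    pmap = classify_grid(img, UniformClassifier(), cell_um)
    amap = accuracy_map(pmap, truth) if truth else None
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    save_probability_map(out / "probability_map.json", pmap, amap,
                         heatmap_path=out / "probability_map.png")
    _stamp(out, cfg)
    typer.echo(f"wrote {out / 'probability_map.json'}")


@app.command()
def run(out: Path = typer.Option(...),
        n: int = typer.Option(8), image_size: int = 128,
        iterations: int = 200, tile_size: int = 64,
        seed: int = 0):
    """End-to-end smoke chain: simulate -> train -> translate -> evaluate."""
    cfg = RunConfig("run", {"out": str(out)},
                    {"n": n, "iterations": iterations}, seed)
    out = Path(out)
    result = run_end_to_end(out, n=n, image_size=image_size,
                            iterations=iterations, tile_size=tile_size,
                            seed=seed)
    _stamp(out, cfg, result)
    typer.echo(json.dumps(result, indent=1, default=str))


def run_end_to_end(out_dir, n: int = 8, image_size: int = 128,
                   iterations: int = 200, tile_size: int = 64,
                   seed: int = 0) -> dict:
    """Simulate a phantom dataset, train the translator on the train split,
    translate the held-out pairs and report their morphometry. Returns a
    summary dict; artifacts land under ``out_dir``."""
    out_dir = Path(out_dir)
    data_dir = out_dir / "data"
    template = PhantomParams(image_size=image_size)
    generate_dataset(n, data_dir, template=template, seed=seed)
    xs, ys, pairs = _load_dataset(data_dir / "manifest.json")
    train_pairs, test_pairs, policy = split_dataset(pairs, (1, 4), seed)
    translator = NOCHTranslator(iterations=iterations, tile_size=tile_size,
                                validation_every=max(1, iterations // 4),
                                seed=seed)
    translator.fit([p[1] for p in train_pairs], [p[2] for p in train_pairs])
    seg = NucleiSegmenter()
    reports = []
    trans_dir = out_dir / "translations"
    trans_dir.mkdir(parents=True, exist_ok=True)
    for entry, x_img, y_img in test_pairs:
        virt = translator.translate_one(x_img)
        write_image(trans_dir / (Path(entry["path"]).stem + "_noch.png"), virt)
        dec = stain_deconvolve(virt)
        summary = seg.summarize(virt)
        reports.append({"image": entry["path"],
                        "prop_hematoxylin": dec.prop_hematoxylin,
                        "n_nuclei": summary.n_nuclei,
                        "pixel_mae_vs_truth": float(
                            np.abs(virt.pixels - y_img.pixels).mean())})
    return {"n_train": len(train_pairs), "n_test": len(test_pairs),
            "split_policy": policy,
            "selected_checkpoint": translator.record_.selected_checkpoint,
            "test_reports": reports}


def main():  # pragma: no cover - console entry
    app()


if __name__ == "__main__":  # pragma: no cover
    sys.exit(app())
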