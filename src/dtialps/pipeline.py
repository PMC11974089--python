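"""End-to-end reproducible pipeline: phantom -> fit -> ALPS -> volumes -> stats.

Every stage writes its artifacts under the configured output directory and
the run ends with a manifest of SHA-256 file hashes, so reruns with the
same config and seed can be verified bit-identical. NIfTI artifacts are
written uncompressed (.nii) so the hashes are a function of the voxel data
and header alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from dtialps.acquisition import make_gradient_table, write_bval_bvec
from dtialps.alps import auto_place_vois, subject_alps
from dtialps.cohort import CohortSpec, simulate_cohort, write_cohort_tsv, cohort_to_frame
from dtialps.phantom import PhantomSpec, synthesize_dwi, write_dwi
from dtialps.stats import full_report, report_frames
from dtialps.tensorfit import fit_tensor, scalar_maps, write_map, write_tensor
from dtialps.volumetrics import subject_volumes, write_label_mask

log = logging.getLogger("dtialps")


@dataclass
class RunConfig:
    """Pipeline configuration; loadable from YAML or JSON."""

    seed: int = 0
    outdir: str = "dtialps_run"
    n_directions: int = 48
    b_value: float = 1000.0
    snr: float | None = 30.0
    phantom_alpha_tumor_side: float = 0.7
    with_tumor: bool = True
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    do_phantom: bool = True
    do_fit: bool = True
    do_alps: bool = True
    do_volumes: bool = True
    do_stats: bool = True
    verbosity: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        if not isinstance(data, dict):
            raise ValueError(f"config {path} did not parse to a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages; returns the artifact manifest dict."""
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    timings: dict[str, float] = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            timings[name] = round(time.perf_counter() - t0, 3)
            log.info("stage %s done in %.2fs", name, timings[name])

        return deco

    tf = {}
    mask_holder = {}

    if config.do_phantom:
        @stage("phantom")
        def _phantom():
            gtab = make_gradient_table(config.n_directions, config.b_value, 1, config.seed)
            spec = PhantomSpec(snr=config.snr, seed=config.seed, alpha_left=config.phantom_alpha_tumor_side)
            if config.with_tumor:
                spec = spec.with_tumor()
            dwi, labmask = synthesize_dwi(spec, gtab)
            write_dwi(dwi, out / "dwi.nii")
            write_bval_bvec(gtab, out / "dwi.bval", out / "dwi.bvec")
            write_label_mask(labmask, out / "labels.nii", out / "labels.json")
            mask_holder["labels"] = labmask
            mask_holder["dwi"] = dwi
            artifacts.extend([out / "dwi.nii", out / "dwi.bval", out / "dwi.bvec", out / "labels.nii", out / "labels.json"])

    if config.do_fit and "dwi" in mask_holder:
        @stage("fit")
        def _fit():
            field_ = fit_tensor(mask_holder["dwi"], mask_holder["labels"].data > 0, method="wls")
            maps = scalar_maps(field_)
            write_tensor(field_, out / "tensor.nii")
            write_map(maps.fa, field_.affine, out / "fa.nii")
            write_map(maps.md, field_.affine, out / "md.nii")
            tf["field"] = field_
            artifacts.extend([out / "tensor.nii", out / "fa.nii", out / "md.nii"])

    if config.do_alps and "field" in tf:
        @stage("alps")
        def _alps():
            vois = auto_place_vois(mask_holder["labels"].data)
            vois.to_json(out / "vois.json")
            res = subject_alps(tf["field"], vois, tumor_side="left" if config.with_tumor else None)
            payload = {
                "index_by_side": res.index_by_side,
                "bilateral_mean": res.bilateral_mean,
                "side_labels": res.side_labels,
                "diffusivities": res.diffusivities,
            }
            (out / "alps.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
            artifacts.extend([out / "vois.json", out / "alps.json"])

    if config.do_volumes and "labels" in mask_holder:
        @stage("volumes")
        def _volumes():
            vols = subject_volumes(mask_holder["labels"])
            (out / "volumes.json").write_text(
                json.dumps(dataclasses.asdict(vols), indent=2, sort_keys=True) + "\n"
            )
            artifacts.append(out / "volumes.json")

    if config.do_stats:
        @stage("stats")
        def _stats():
            spec = CohortSpec(seed=config.seed, **config.cohort)
            records = simulate_cohort(spec)
            write_cohort_tsv(records, out / "cohort.tsv")
            report = full_report(cohort_to_frame(records))
            frames = report_frames(report)
            for name, frame in frames.items():
                path = out / f"report_{name}.tsv"
                frame.to_csv(path, sep="\t", index=False)
                artifacts.append(path)
            artifacts.append(out / "cohort.tsv")

    # timings are logged but kept out of the manifest so that reruns with the
    # same config and seed produce byte-identical manifests
    (out / "timings.log").write_text(
        "".join(f"{k}\t{v:.3f}s\n" for k, v in timings.items())
    )
    manifest = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "files": {p.name: _sha256(p) for p in sorted(set(artifacts))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
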