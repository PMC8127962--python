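"""End-to-end imaging pipeline: correct -> detect -> coloc -> pheno.

Deterministic under a fixed config and seed; every output CSV carries the
config digest and seed in a comment header line so runs are auditable.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import coloc, detect, imgproc, pheno, synth
from .config import PipelineConfig

log = logging.getLogger(__name__)


def _write_csv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    header = f"# granulekit config={config.digest()} seed={config.seed}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_output_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def run_imaging_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    use_synth: bool = True,
    field_params: "synth.FieldParams | None" = None,
) -> dict[str, Path]:
    """Run the imaging track on synthetic fields and write result CSVs.

    Returns a mapping of output names to paths.  Only synthetic input is
    wired here; file-based input goes through the stage CLIs.
    """
    if not use_synth:
        raise NotImplementedError(
            "directory input is handled by the per-stage commands; "
            "use --synth for the end-to-end run"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    params = field_params or synth.FieldParams(
        pixel_size=config.pixel_size,
        illumination_magnitude=0.2,
        illumination_order=config.illumination_order,
        read_noise_sd=15.0,
        recruiting_fraction=0.9,
    )
    gate = (config.gate_min, config.gate_max)

    granule_frames, match_frames, fraction_rows, enrich_frames = [], [], [], []
    cell_records: list[pheno.CellRecord] = []
    for i in range(config.n_images):
        seed_i = config.seed * 10_000 + i
        fi, gt = synth.generate_field_image(params, seed=seed_i)
        fi.image_id = f"synth-{config.seed}-{i}"
        inside = fi.cell_mask > 0
        illum = {
            ch: imgproc.estimate_illumination_field(
                fi.channels[ch], inside, poly_order=config.illumination_order
            )
            for ch in fi.channels
        }
        corrected = imgproc.correct_image(fi, illumination=illum)

        set_a = detect.segment_granules(
            corrected, "A", gate=gate, per_cell=config.per_cell_threshold
        )
        set_b = detect.segment_granules(
            corrected, "B", gate=gate, per_cell=config.per_cell_threshold
        )
        granule_frames.append(set_a.to_frame())
        granule_frames.append(set_b.to_frame())

        result = coloc.match_granules(set_a, set_b, cutoff_um=config.coloc_cutoff)
        match_frames.append(result.matches_frame())
        try:
            per_cell, pooled = coloc.colocalization_fraction(result, reference="A")
        except ValueError:
            per_cell, pooled = {}, float("nan")
        for cid, pct in sorted(per_cell.items()):
            fraction_rows.append(
                {"image_id": fi.image_id, "cell_id": cid, "percent_colocalized": pct}
            )
        enr = coloc.fold_enrichment(set_a, corrected.channels["B"], corrected.cell_mask)
        enrich_frames.append(enr.per_granule)

        by_cell = set_a.by_cell()
        for cid in set_a.cell_ids:
            cell_records.append(
                pheno.CellRecord(
                    image_id=fi.image_id,
                    cell_id=cid,
                    condition="synthetic",
                    granule_diameters=[
                        g.equivalent_diameter_um for g in by_cell.get(cid, [])
                    ],
                )
            )

    outputs = {
        "granules": pd.concat(granule_frames, ignore_index=True),
        "matches": pd.concat(match_frames, ignore_index=True),
        "coloc_fractions": pd.DataFrame(
            fraction_rows, columns=["image_id", "cell_id", "percent_colocalized"]
        ),
        "enrichment": pd.concat(enrich_frames, ignore_index=True),
        "positive_fraction": pheno.granule_positive_fraction(
            cell_records, threshold=config.positive_threshold
        ),
    }
    paths: dict[str, Path] = {}
    for name, df in outputs.items():
        path = out / f"{name}.csv"
        _write_csv(df, path, config)
        paths[name] = path
        log.info("wrote %s (%d rows)", path, len(df))

    run_log = out / "run_log.txt"
    run_log.write_text(
        "granulekit imaging pipeline\n"
        f"config_digest: {config.digest()}\n"
        + "".join(f"{k}: {v}\n" for k, v in sorted(vars(config).items()))
    )
    paths["run_log"] = run_log
    return paths
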