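"""End-to-end analysis pipeline: charge profiles, block segmentation,
blockiness metrics, variant design, C_sat fitting, metric-C_sat
correlation and the phosphorylation-effect scan, driven by one
:class:`~chargeblocks.config.RunConfig` and a set of input files.

All inputs are validated before the first stage runs; outputs are
deterministic TSVs plus a JSON manifest (tool version, config hash,
input hashes) sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .blockiness import compute_report, segment_blocks
from .charge import ChargeModel, charge_profile
from .config import RunConfig
from .phase import compare_metrics, correlate, fit_csat, read_turbidity
from .scan import scan, scan_to_frame
from .sequences import (
    PhosphositeTable,
    attach_sites,
    read_fasta,
    read_phosphosites,
    write_fasta,
)
from .variants import apply_nonphospho, apply_phosphomimetic

ALL_STAGES = (
    "profile",
    "blocks",
    "metrics",
    "design",
    "csat-fit",
    "correlate",
    "scan",
)


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_idr_ranges(path: Path) -> dict[str, tuple[int, int]]:
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "start", "end"}
    if not required <= set(df.columns):
        raise PipelineError(f"IDR range table must have columns {sorted(required)}")
    return {
        str(r.protein_id): (int(r.start), int(r.end)) for r in df.itertuples()
    }


def run_pipeline(
    config: RunConfig,
    inputs: dict[str, str | Path],
    stages: tuple[str, ...] = ALL_STAGES,
) -> dict:
    """Run the requested stages and return the manifest.

    ``inputs`` maps input kinds to paths: ``fasta`` (required),
    ``phosphosites`` (TSV, optional), ``turbidity`` (TSV, required for
    csat-fit/correlate), ``idr_ranges`` (TSV, required for scan).  Any
    missing or unreadable input needed by a requested stage fails before
    the first stage executes.
    """
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise PipelineError(f"unknown stages {sorted(unknown)}")
    model = ChargeModel(phospho_charge=config.phospho_charge)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # -- resolve and validate every needed input up front
    paths: dict[str, Path] = {}
    needed = {"fasta"}
    if {"csat-fit", "correlate"} & set(stages):
        needed.add("turbidity")
    if "scan" in stages:
        needed.add("idr_ranges")
        needed.add("phosphosites")
    for kind in needed:
        if kind not in inputs:
            raise PipelineError(f"missing required input {kind!r}")
    for kind, p in inputs.items():
        p = Path(p)
        if not p.exists():
            raise PipelineError(f"input {kind!r} not found: {p}")
        paths[kind] = p

    sequences = read_fasta(paths["fasta"])
    table: PhosphositeTable | None = None
    if "phosphosites" in paths:
        table = read_phosphosites(paths["phosphosites"])  # fails fast if corrupt
        annotated = []
        for seq in sequences:
            if len(table.for_protein(seq.id)) > 0:
                annotated.append(attach_sites(seq, table, direction="up"))
            else:
                annotated.append(seq)
        sequences = annotated
    curves = read_turbidity(paths["turbidity"]) if "turbidity" in paths else None
    idr_ranges = _read_idr_ranges(paths["idr_ranges"]) if "idr_ranges" in paths else None

    outputs: dict[str, str] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        outputs[name] = _sha256(path)

    if "profile" in stages:
        frames = []
        for seq in sequences:
            for state in ("interphase", "mitotic"):
                prof = charge_profile(seq, window=config.window_plot, state=state, model=model)
                df = prof.to_frame()
                df.insert(0, "sequence_id", seq.id)
                df.insert(1, "state", state)
                frames.append(df)
        emit("profiles.tsv", pd.concat(frames, ignore_index=True))

    if "blocks" in stages:
        rows = []
        for seq in sequences:
            for state in ("interphase", "mitotic"):
                prof = charge_profile(seq, window=config.window_block, state=state, model=model)
                for b in segment_blocks(prof, config.block_area_threshold):
                    rows.append(
                        {
                            "sequence_id": seq.id,
                            "state": state,
                            "start": b.start,  # 1-based inclusive
                            "end": b.end,
                            "sign": b.sign,
                            "area": b.area,
                            "size": b.size,
                        }
                    )
        emit("blocks.tsv", pd.DataFrame(rows, columns=[
            "sequence_id", "state", "start", "end", "sign", "area", "size"
        ]))

    if "metrics" in stages:
        rows = []
        for seq in sequences:
            for state in ("interphase", "mitotic"):
                rep = compute_report(
                    seq,
                    state=state,
                    window_block=config.window_block,
                    threshold=config.block_area_threshold,
                    kappa_blob=config.kappa_blob,
                    model=model,
                )
                rows.append(rep.__dict__)
        emit("metrics.tsv", pd.DataFrame(rows))

    if "design" in stages:
        variants = []
        prov_rows = []
        for seq in sequences:
            if not seq.phosphosites:
                continue
            for rec in (apply_phosphomimetic(seq), apply_nonphospho(seq)):
                variants.append(rec.sequence)
                prov_rows.append(
                    {
                        "parent_id": rec.parent_id,
                        "name": rec.name,
                        "provenance": json.dumps(rec.provenance, sort_keys=True),
                    }
                )
        fasta_path = outdir / "design.fasta"
        write_fasta(variants, fasta_path)
        outputs["design.fasta"] = _sha256(fasta_path)
        emit("design_provenance.tsv", pd.DataFrame(prov_rows))

    fits = None
    if "csat-fit" in stages:
        fits = [fit_csat(c) for c in curves]
        emit(
            "csat_fits.tsv",
            pd.DataFrame(
                [
                    {
                        "construct": f.construct_id,
                        "c_sat_uM": f.c_sat,
                        "od_max": f.od_max,
                        "steepness": f.steepness,
                        "baseline": f.baseline,
                        "rss": f.rss,
                        "converged": f.converged,
                    }
                    for f in fits
                ]
            ),
        )

    if "correlate" in stages:
        if fits is None:
            fits = [fit_csat(c) for c in curves]
        csat_by_id = {
            f.construct_id: f.c_sat for f in fits if f.converged and f.c_sat > 0
        }
        seq_by_id = {s.id: s for s in sequences}
        ids = sorted(set(csat_by_id) & set(seq_by_id))
        if len(ids) < 3:
            raise PipelineError(
                "correlate needs >= 3 constructs present in both the FASTA "
                f"and the turbidity data; found {len(ids)}"
            )
        metric_vectors = {"B_LC": [], "D_seg": [], "net_charge": []}
        for i in ids:
            rep = compute_report(
                seq_by_id[i],
                state="interphase",
                window_block=config.window_block,
                threshold=config.block_area_threshold,
                kappa_blob=config.kappa_blob,
                model=model,
            )
            metric_vectors["B_LC"].append(rep.blc)
            metric_vectors["D_seg"].append(rep.dseg)
            metric_vectors["net_charge"].append(rep.net_charge)
        csats = [csat_by_id[i] for i in ids]
        cors = [
            correlate(v, csats, name, construct_ids=tuple(ids))
            for name, v in metric_vectors.items()
        ]
        ranking = compare_metrics(cors)
        ranking = ranking.assign(
            blockiness_outranks_net_charge=ranking.attrs[
                "blockiness_outranks_net_charge"
            ]
        )
        emit("correlations.tsv", ranking)

    if "scan" in stages:
        records = scan(
            [s.replace(phosphosites=frozenset(), phosphorylated=frozenset()) for s in sequences],
            table,
            idr_ranges,
            neutral_band=config.neutral_band,
            window=config.window_block,
            threshold=config.block_area_threshold,
            model=model,
        )
        emit("scan.tsv", scan_to_frame(records))

    manifest = {
        "tool": "chargeblocks",
        "version": __version__,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "inputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in paths.items()},
        "stages": list(stages),
        "outputs": outputs,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
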