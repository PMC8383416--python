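"""End-to-end pipeline: detect circles, build references, derive the m6A
cutoff, binarize, compute tracks, profiles, single-molecule calls and COA.

Every stage is also available standalone through the library (and CLI); the
pipeline only wires them together and writes a deterministic manifest with
parameters, per-stage record counts and output checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as cio
from . import detect as cdetect
from . import circular as ccirc
from . import threshold as cthresh
from . import profiles as cprof
from . import coa as ccoa

log = logging.getLogger("circlechrom")


@dataclass
class RunConfig:
    """Paths and parameters of a full run; defaults follow the method."""

    genome: str = ""
    alignments: str = ""
    modcalls: str = ""
    genes: str = ""
    control: str | None = None
    expression: str | None = None
    min_seg_len: int = 1000
    size_range: tuple[int, int] = (50, 100_000)
    cluster_tol: int = 50
    pad: int = 10_000
    rotation: int | None = None  # None: center the junction
    cutoff: float | str = 0.53   # a float, or "fit" for the mixture crossover
    bin: int = 50
    step: int = 5
    flank: int = 500
    window: int = 200
    min_reads: int = 5
    min_A: int = 2
    prior_open: float = 0.5
    seed: int = 0
    log_level: str = "INFO"

    def validate(self):
        for name in ("genome", "alignments", "modcalls", "genes"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"input {name!r} missing: {p!r}")
        if isinstance(self.cutoff, str):
            if self.cutoff != "fit":
                raise ValueError(f"cutoff must be a number or 'fit', got {self.cutoff!r}")
            if self.control is None:
                raise ValueError(
                    "cutoff='fit' requires a control mod-call table for evaluation "
                    "(pass control=...)"
                )
        elif not 0 < float(self.cutoff) < 1:
            raise ValueError(f"numeric cutoff must be in (0, 1), got {self.cutoff}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "size_range" in data:
            data["size_range"] = tuple(data["size_range"])
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages; write outputs and a manifest into ``outdir``.

    On a stage failure, partial outputs are kept and a FAILED marker naming
    the stage is written before the error propagates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    log.addHandler(handler)
    log.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))

    manifest: dict = {
        "package_version": __version__,
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": {},
    }
    stage = "configure"
    try:
        config.validate()

        stage = "load"
        genome = cio.read_genome_fasta(config.genome)
        alignments = cio.read_alignment_table(config.alignments)
        calls = cio.read_modcall_table(config.modcalls)
        genes = cio.read_gene_bed(config.genes)
        if config.expression:
            cio.attach_expression(genes, config.expression)
        control = cio.read_modcall_table(config.control) if config.control else None
        manifest["stages"]["load"] = {
            "n_segments": int(len(alignments)),
            "n_calls": int(len(calls)),
            "n_genes": len(genes),
            "n_control_calls": int(len(control)) if control is not None else 0,
        }

        stage = "detect"
        candidates = cdetect.detect_junctions(
            alignments, config.min_seg_len, config.size_range
        )
        records = cdetect.cluster_junctions(candidates, config.cluster_tol)
        cio.write_ecdna_bed(records, outdir / "ecdna.bed")
        cio.write_ecdna_json(records, outdir / "ecdna.json")
        manifest["stages"]["detect"] = {
            "n_candidates": len(candidates),
            "n_records": len(records),
        }
        log.info("detect: %d candidates -> %d records", len(candidates), len(records))

        stage = "build-ref"
        refs = [
            ccirc.build_reference(genome, rec, config.rotation, config.pad, name=f"ecdna_{k}")
            for k, rec in enumerate(records)
        ]
        cio.write_fasta({r.name: r.seq for r in refs}, outdir / "ecdna_refs.fasta")
        ccirc.write_sidecar(refs, outdir / "ecdna_refs.json")
        manifest["stages"]["build-ref"] = {"n_references": len(refs)}

        stage = "cutoff"
        fit = cthresh.fit_probability_mixture(calls["prob"].to_numpy(), seed=config.seed)
        if config.cutoff == "fit":
            if not fit.converged or fit.cutoff is None:
                raise ValueError(f"mixture fit unusable for cutoff: {fit.diagnostic}")
            cutoff = float(fit.cutoff)
        else:
            cutoff = float(config.cutoff)
        report = {"cutoff": cutoff, "source": "fit" if config.cutoff == "fit" else "fixed"}
        if control is not None and fit.converged:
            report.update(
                cthresh.evaluate_cutoff(
                    calls["prob"].to_numpy(), control["prob"].to_numpy(), cutoff, fit
                )
            )
        fit.to_json(outdir / "mixture.json")
        with open(outdir / "cutoff_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest["stages"]["cutoff"] = {
            "cutoff": round(cutoff, 6),
            "converged": bool(fit.converged),
        }

        stage = "binarize"
        calls = cthresh.binarize_calls(calls, cutoff)
        manifest["stages"]["binarize"] = {
            "n_methylated": int(calls["methylated"].sum()),
            "n_calls": int(len(calls)),
        }

        stage = "track"
        chrom_lengths = {name: g.length for name, g in genome.items()}
        ecdna_read_ids = {rid for rec in records for rid in rec.read_ids}
        linear_calls = calls[~calls["read_id"].isin(ecdna_read_ids)]
        n_bins = 0
        for mode in ("both", "plus", "minus"):
            tracks = [
                cprof.methylation_ratio_track(
                    linear_calls, name, length, config.bin, config.step, mode
                )
                for name, length in sorted(chrom_lengths.items())
            ]
            cio.write_bedgraph(tracks, outdir / f"linear_{mode}.bedgraph")
            n_bins += sum(t.starts.size for t in tracks)
        circle_calls = []
        for rec, ref in zip(records, refs):
            cc = ccirc.calls_to_circular(calls, ref, read_ids=rec.read_ids)
            circle_calls.append((ref, cc))
        for mode in ("both", "plus", "minus"):
            tracks = [
                cprof.methylation_ratio_track(cc, ref.name, len(ref.seq), config.bin, config.step, mode)
                for ref, cc in circle_calls
                if len(cc)
            ]
            if tracks:
                cio.write_bedgraph(tracks, outdir / f"ecdna_{mode}.bedgraph")
        manifest["stages"]["track"] = {"n_linear_bins": n_bins, "n_circles_with_calls": sum(1 for _, cc in circle_calls if len(cc))}

        stage = "metagene"
        meta = {}
        for anchor in ("TSS", "TES"):
            prof = cprof.metagene_profile(
                linear_calls, genes, anchor, config.flank, config.bin, config.step
            )
            prof.to_frame().to_csv(outdir / f"metagene_{anchor.lower()}.tsv", sep="\t", index=False)
            meta[anchor] = prof.n_genes
        manifest["stages"]["metagene"] = {"n_genes_tss": meta["TSS"], "n_genes_tes": meta["TES"]}

        stage = "junction-profile"
        n_junction_offsets = 0
        with_cov = [(r, cc) for r, cc in circle_calls if len(cc)]
        if with_cov:
            try:
                jprof = cprof.junction_profile(with_cov, config.flank, config.bin, config.step)
                jprof.to_frame().to_csv(outdir / "junction_profile.tsv", sep="\t", index=False)
                n_junction_offsets = int(np.sum(~np.isnan(jprof.values)))
            except ValueError:
                pass  # no junction-spanning coverage at this depth
        manifest["stages"]["junction-profile"] = {"n_offsets": n_junction_offsets}

        stage = "molecule"
        molecules_by_ref: dict[str, list] = {}
        frames = []
        for name, length in sorted(chrom_lengths.items()):
            mols = cprof.molecule_calls_for_ref(
                linear_calls, fit, name, length, config.window, config.min_A, config.prior_open
            )
            molecules_by_ref[name] = mols
            frames.extend(m.to_frame() for m in mols)
        for ref, cc in circle_calls:
            if len(cc) == 0:
                continue
            mols = cprof.molecule_calls_for_ref(
                cc, fit, ref.name, len(ref.seq), config.window, config.min_A, config.prior_open
            )
            molecules_by_ref[ref.name] = mols
            frames.extend(m.to_frame() for m in mols)
        mol_df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        mol_df.to_csv(outdir / "molecule_calls.tsv", sep="\t", index=False, float_format="%.6g")
        manifest["stages"]["molecule"] = {
            "n_molecules": sum(len(v) for v in molecules_by_ref.values())
        }

        stage = "coa"
        n_entries = {}
        for name, mols in sorted(molecules_by_ref.items()):
            if len(mols) < config.min_reads:
                continue
            mat = ccoa.coaccessibility_matrix(mols, config.min_reads)
            mat.to_long_frame().to_csv(
                outdir / f"coa_{name}.tsv", sep="\t", index=False, float_format="%.6g"
            )
            n_entries[name] = int(np.sum(~np.isnan(mat.values)))
        manifest["stages"]["coa"] = {"n_defined_entries": n_entries}

        stage = "manifest"
        outputs = sorted(
            p.name for p in outdir.iterdir()
            if p.is_file() and p.name not in ("run.log", "manifest.json", "FAILED")
        )
        manifest["outputs"] = {name: _sha256(outdir / name) for name in outputs}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        log.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, exc) from exc
    finally:
        log.removeHandler(handler)
        handler.close()
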