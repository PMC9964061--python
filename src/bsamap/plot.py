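"""Diagnostic plots for a linkage scan: allele-frequency tracks per pool
with their moving averages, and the Fisher p-value track with the
Bonferroni threshold line."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .mapping import MapResult


def plot_map_result(result: MapResult, out_dir: str | Path, fmt: str = "png") -> list[Path]:
    """One figure per chromosome (markers + smoothed tracks + threshold)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for chrom, tt in result.tests.items():
        fig, axes = plt.subplots(3, 1, figsize=(9, 7), sharex=True)
        mb = tt.pos / 1e6
        axes[0].plot(mb, tt.wt_freq, ".", ms=1.5, color="#77aadd", alpha=0.4)
        axes[1].plot(mb, tt.mut_freq, ".", ms=1.5, color="#77aadd", alpha=0.4)
        sm_wt = result.smoothed_wt_freq.get(chrom)
        sm_mut = result.smoothed_mut_freq.get(chrom)
        for ax in axes[:2]:
            if sm_wt is not None and len(sm_wt):
                ax.plot(sm_wt.anchor_pos / 1e6, sm_wt.value, color="green", lw=1.2,
                        label="wild-type pool (smoothed)")
            if sm_mut is not None and len(sm_mut):
                ax.plot(sm_mut.anchor_pos / 1e6, sm_mut.value, color="deeppink", lw=1.2,
                        label="mutant pool (smoothed)")
            ax.set_ylim(-0.02, 1.02)
        axes[0].set_ylabel("alt freq (wt pool)")
        axes[1].set_ylabel("alt freq (mut pool)")
        axes[0].legend(fontsize=7, loc="upper right")

        axes[2].semilogy(mb, tt.p_value.clip(1e-300), ".", ms=1.5, color="#77aadd", alpha=0.4)
        sm_p = result.smoothed_p.get(chrom)
        if sm_p is not None and len(sm_p):
            axes[2].semilogy(sm_p.anchor_pos / 1e6, sm_p.value, color="red", lw=1.2,
                             label="weighted geometric mean")
        axes[2].axhline(result.threshold, ls="--", color="black", lw=0.8,
                        label="Bonferroni threshold")
        axes[2].set_ylabel("Fisher p")
        axes[2].set_xlabel(f"{chrom} position (Mb)")
        axes[2].legend(fontsize=7, loc="lower right")
        if chrom == result.interval.chrom:
            for ax in axes:
                ax.axvspan(result.interval.start_pos / 1e6, result.interval.end_pos / 1e6,
                           color="orange", alpha=0.15)
        fig.suptitle(f"{chrom}: pooled allele frequencies and Fisher p-values")
        fig.tight_layout()
        path = out / f"scan_{chrom}.{fmt}"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths.append(path)
    return paths
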