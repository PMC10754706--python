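#!/usr/bin/env python
"""Inter-brain amplitude-envelope-correlation analysis on a simulated cohort.

With the default generator, envelope coupling is 0 in both conditions,
so this run demonstrates the null pattern: near-zero AECs in every
region, no condition differences in the paired tests or the epoch-level
mixed models, and no channel pair surviving the max-t permutation with
FDR.  Tables land in results/inter/ (the AEC table mirrors the
region x condition mean/SD/range + t/p layout).
"""

from pathlib import Path

from dyadssvep.pipeline import RunConfig, run_inter

OUT = Path("results/inter")


def main() -> None:
    config = RunConfig(seed=12, n_dyads=12, n_perm=500)
    report = run_inter(config)
    report.write(OUT)

    print(
        f"{report.n_dyads_included}/{config.n_dyads} dyads had >= "
        f"{config.min_mutual} mutual epochs per condition"
    )
    print("\nAEC by region (r scale, inverse-transformed):")
    print(report.aec_table.round(3).to_string(index=False))
    for reg, res in report.lmm.items():
        row = res.anova.iloc[0]
        print(
            f"epoch-level LMM ({reg} channels): "
            f"F({row['df_num']:.0f},{row['df_den']:.0f}) = {row['F']:.2f}, "
            f"p = {row['p']:.2f}"
        )
    print(
        f"channel-pair permutation: {int(report.pair_perm.reject.sum())} of "
        f"{report.pair_perm.p.size} pairs significant after FDR"
    )
    print(f"\ntables -> {OUT}")


if __name__ == "__main__":
    main()
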