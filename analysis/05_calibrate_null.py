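"""Monte-Carlo calibration of SFI false-positive rates under three nulls.

Simulates 100 000 random 10-point correlation profiles under each null
(uniform on (-0.5, 0.5); truncated normal N(0, 0.1); truncated normal
N(0, 0.3)), fits the constrained sinusoid to every profile, and
tabulates the fraction of null profiles reaching SFI < 0.05 / 0.10 /
0.15 / 0.20, with Monte-Carlo standard errors.  Also evaluates the
left-tail empirical rate at SFI = 0.19, the fit statistic the original
study reported for its polygenic-score profile.  Writes one TSV per
null under results/calibration/.
"""

from pathlib import Path

from valuewave.calibration import (
    calibrate,
    empirical_pvalue,
    normal_null,
    uniform_null,
)

OUT = Path("results/calibration")
N = 100_000
SEED = 0


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    specs = {
        "uniform": uniform_null(n_samples=N, seed=SEED),
        "normal_sd0.1": normal_null(sd=0.1, n_samples=N, seed=SEED + 1),
        "normal_sd0.3": normal_null(sd=0.3, n_samples=N, seed=SEED + 2),
    }
    tables = {}
    for name, spec in specs.items():
        tables[name] = calibrate(spec)
        frame = tables[name].to_frame()
        frame.to_csv(OUT / f"{name}.tsv", sep="\t", index=False)
        print(f"{name} null ({N} profiles):")
        for _, row in frame.iterrows():
            print(f"  SFI < {row.threshold:.2f}: {row.fp_percent:.3f}% "
                  f"(MC SE {100 * row.mc_se:.3f})")
    p, se = empirical_pvalue(0.19, tables["uniform"])
    print(f"\nempirical rate at SFI = 0.19 (uniform null): "
          f"{100 * p:.2f}% (MC SE {100 * se:.3f})")
    print(f"tables written under {OUT}/")


if __name__ == "__main__":
    main()
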