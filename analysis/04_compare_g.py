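"""Pairwise G-matrix comparisons between populations.

Loads the saved posteriors and computes, per pair: Ovaskainen's D,
the difference in variance along Gmax, the Krzanowski angle between the
Gmax axes, and the difference in total genetic variance (sum-volume) —
each with a 95% HPD interval and a significance decision.
"""

from pathlib import Path

from qgclone import gcompare, gfit

ROOT = Path(__file__).resolve().parents[1]
SEED = 1
PAIRS = (("Chile", "UK"), ("Chile", "ME"), ("UK", "ME"))


def main() -> None:
    posts = {}
    for pop in ("Chile", "UK", "ME"):
        d = ROOT / "results" / f"gposterior_{pop}"
        if not d.exists():
            raise SystemExit("run analysis/03_fit_g_matrices.py first")
        posts[pop] = gfit.GPosterior.load(d)

    for k, (a, b) in enumerate(PAIRS):
        comp = gcompare.compare_pair(posts[a], posts[b], seed=SEED * 100 + k)
        comp.save(ROOT / "results" / f"comparison_{a}_{b}.json")
        print(f"\n{a} vs {b}:")
        for label, metric in (
            ("Ovaskainen D", comp.D),
            ("Δ variance Gmax", comp.delta_var_gmax),
            ("angle between Gmax (°)", comp.angle_gmax),
            ("Δ sum-volume", comp.delta_total_variance),
        ):
            star = " *" if metric.significant else ""
            print(
                f"  {label:<24} {metric.estimate:+.3f} "
                f"[{metric.hpd[0]:+.3f}, {metric.hpd[1]:+.3f}]{star}"
            )
    print("\n(* = significant: HPD excludes 0, or exceeds the permutation null)")


if __name__ == "__main__":
    main()
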