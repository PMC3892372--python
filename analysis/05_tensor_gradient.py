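"""Genetic covariance tensor across the invasion gradient Chile → UK → ME.

Decomposes the among-population covariance of the three G-matrices into
eigentensors (per posterior draw, summarized by modes and 95% HPDs):
how many independent axes of G change there are, which trait drives the
leading axis, and how much genetic variance each site holds along it.
"""

from pathlib import Path

from qgclone import gfit, gtensor

ROOT = Path(__file__).resolve().parents[1]
GRADIENT = ("Chile", "UK", "ME")


def main() -> None:
    posts = []
    for pop in GRADIENT:
        d = ROOT / "results" / f"gposterior_{pop}"
        if not d.exists():
            raise SystemExit("run analysis/03_fit_g_matrices.py first")
        posts.append(gfit.GPosterior.load(d))

    decomp = gtensor.tensor_analysis(posts, seed=1)
    decomp.save(ROOT / "results" / "tensor.json")
    rep = decomp.to_dict()

    print("gradient:", " → ".join(GRADIENT))
    print("\n(A) variance among G-matrices captured by each eigentensor:")
    for row in rep["A_variance_proportions"]:
        print(
            f"  tensor {row['tensor']}: {row['mode']:.2f} "
            f"[{row['lower']:.3f}, {row['upper']:.3f}]"
        )
    print("\n(B) directional change in genetic variance per trait (tensor 1):")
    for row in rep["B_delta_va_tensor1"]:
        print(
            f"  {row['trait']:>14}: {row['mode']:+.2f} "
            f"[{row['lower']:+.2f}, {row['upper']:+.2f}]"
        )
    print("\n(C) genetic variance at each site along tensor 1:")
    for row in rep["C_site_variance_T1"]:
        print(
            f"  {row['population']:>6}: {row['mode']:.3f} "
            f"[{row['lower']:.3f}, {row['upper']:.3f}]"
        )
    print("\nwrote results/tensor.json")


if __name__ == "__main__":
    main()
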