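"""Score fingerprint overlap with Tversky similarity.

Tversky similarity S(X, Y) = |X∩Y| / (|X∩Y| + a|X\\Y| + b|Y\\X|)
generalizes the Tanimoto coefficient (a = b = 1).  With a = 0.5 and
b = 0.01 the penalty for reference-set bits missing from the query is
nearly dropped, rewarding substructure matches — the setting used when
steering molecule generation toward a target fingerprint.
"""

from paddyfield import tversky

query = {1, 4, 9, 16, 25, 36}
reference = {1, 4, 9, 49, 64, 81, 100}

print(f"query bits:     {sorted(query)}")
print(f"reference bits: {sorted(reference)}")
print(f"Tanimoto (a=b=1):          {tversky(query, reference, 1, 1):.4f}")
print(f"Tversky (a=0.5, b=0.01):   {tversky(query, reference, 0.5, 0.01):.4f}")
print(
    "The asymmetric coefficients raise the score because missing reference "
    "bits are barely penalized; identical sets always score 1."
)
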