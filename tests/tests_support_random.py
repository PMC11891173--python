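"""Shared helper: random binary Newick strings for round-trip tests."""

import numpy as np


def random_binary_newick(rng: np.random.Generator, n_taxa: int) -> str:
    parts = [f"t{i}:{rng.uniform(0.1, 5):.4f}" for i in range(n_taxa)]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        a, b = parts[i], parts[j]
        merged = f"({a},{b}):{rng.uniform(0.1, 5):.4f}"
        parts = [p for k, p in enumerate(parts) if k not in (i, j)] + [merged]
    return parts[0] + ";"
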