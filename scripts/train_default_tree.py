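"""Regenerate the bundled slur-relevance tree from the synthetic corpus.

Run from the repository root:

    python scripts/train_default_tree.py

Deterministic: the corpus and the fit are both driven by the fixed seed, so
the data file only changes when the generator or trainer changes.
"""

import pathlib

from jtpeak.relevance import train_relevance_tree
from jtpeak.synthetic import generate_slur_corpus

SEED = 7
N = 500

def main():
    examples, labels = generate_slur_corpus(n=N, seed=SEED)
    tree = train_relevance_tree(
        examples,
        labels,
        seed=SEED,
        metadata={"training_set_id": f"synthetic-slur-corpus-n{N}-seed{SEED}"},
    )
    out = (
        pathlib.Path(__file__).resolve().parents[1]
        / "src" / "jtpeak" / "data" / "default_relevance_tree.json"
    )
    tree.to_json(out)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
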