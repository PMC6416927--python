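"""Infer ancestral expression quartiles and binding-site presence.

Runs the repeated-restart consensus reconstruction on every family tree
and reports how many node x item states were callable (majority support
and posterior > 0.5) versus ambiguous.
"""

from common import make_config, RESULTS

from dupdyn.io import read_table
from dupdyn.pipeline import run_pipeline


def main() -> None:
    run_pipeline(make_config(["ancestral"]))
    for name in ("ancestral_calls.tsv", "ancestral_site_calls.tsv"):
        calls = read_table(RESULTS / name, index_col=None)
        called = calls[calls["state"] != "ambiguous"]
        print(f"{name}: {len(called)}/{len(calls)} called "
              f"({len(called) / len(calls):.1%}); "
              f"median posterior {called['posterior'].median():.2f}")


if __name__ == "__main__":
    main()
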