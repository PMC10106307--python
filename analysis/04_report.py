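#!/usr/bin/env python
"""Render figures and the text summary from the completed bundle: mean
latency by price and environment, the paired rod-fixing plot, and the
apathy scatter plots. Pure rendering — no recomputation."""

from pathlib import Path

from fisherman.pipeline import make_report

OUT = Path("results/run-default")


def main() -> None:
    paths = make_report(OUT)
    for name, path in paths.items():
        print(f"{name}: {path}")
    print()
    print(Path(paths["summary"]).read_text())


if __name__ == "__main__":
    main()
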