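"""Constrained integer search that froze the default convolution widths.

The network's printed contract is its total parameter budget (34311 at 7
classes), not the per-layer widths.  This script enumerates width
quadruples and bias/activation options for the fixed architecture
(four 3x3 body convolutions, stride 2 on width increases, adaptive mean
pool, 1x1 convolution head) and prints every configuration whose 7-class
model hits the budget exactly.

The shipped default is (16, 32, 39, 48) with channel-wise parametric
rectifier slopes and no convolution/head biases:

    9*(8*16 + 16*32 + 32*39 + 39*48) + (16+32+39+48) + 48*7 = 34311

Run:  python scripts/width_search.py [--target 34311]
"""

import argparse
import itertools

IN_CHANNELS = 8
N_CLASSES = 7


def parameter_count(widths, prelu, bias, head_bias):
    prev = IN_CHANNELS
    total = 0
    for w in widths:
        total += 9 * prev * w + (w if bias else 0)
        total += {"channel": w, "single": 1, "none": 0}[prelu]
        prev = w
    total += widths[-1] * N_CLASSES + (N_CLASSES if head_bias else 0)
    return total


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--target", type=int, default=34311)
    parser.add_argument("--max-width", type=int, default=128)
    args = parser.parse_args()

    cand = range(4, args.max_width + 1)
    hits = []
    for prelu in ("channel", "single", "none"):
        for bias, head_bias in itertools.product((True, False), repeat=2):
            for w1 in cand:
                for w2 in cand:
                    if w2 < w1:
                        continue
                    for w3 in cand:
                        if w3 < w2:
                            continue
                        for w4 in cand:
                            if w4 < w3:
                                continue
                            if parameter_count(
                                (w1, w2, w3, w4), prelu, bias, head_bias
                            ) == args.target:
                                hits.append(
                                    ((w1, w2, w3, w4), prelu, bias, head_bias)
                                )
    for widths, prelu, bias, head_bias in hits:
        print(
            f"widths={widths} prelu={prelu} conv_bias={bias} "
            f"head_bias={head_bias}"
        )
    print(f"{len(hits)} configurations hit {args.target} exactly")


if __name__ == "__main__":
    main()
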