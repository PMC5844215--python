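import random

import pytest

from snpminer import StatValue
from snpminer.snps import SnpGroup, SnpMention


@pytest.fixture
def rng():
    return random.Random(20240917)


def make_instance(rng, max_snps=5, max_values=5):
    """Random within-sentence pairing instance: SNP groups and P-values with
    non-overlapping spans laid out left to right in random interleaving."""
    n_groups = rng.randint(1, max_snps)
    n_values = rng.randint(1, max_values)
    n_mentions = n_groups + rng.randint(0, 2)  # a few duplicate mentions
    items = ["S"] * n_mentions + ["V"] * n_values
    rng.shuffle(items)

    # assign each mention slot to a group; every group gets at least one
    group_of = list(range(n_groups)) + [
        rng.randrange(n_groups) for _ in range(n_mentions - n_groups)
    ]
    rng.shuffle(group_of)

    pos = 0
    mention_spans: list[tuple[int, tuple[int, int]]] = []
    values: list[StatValue] = []
    mi = 0
    for item in items:
        pos += rng.randint(1, 20)
        width = rng.randint(3, 12)
        span = (pos, pos + width)
        pos += width
        if item == "S":
            mention_spans.append((group_of[mi], span))
            mi += 1
        else:
            values.append(
                StatValue(
                    kind="P",
                    comparator="=",
                    value=float(len(values) + 1) * 1e-8,
                    surface="v",
                    start=span[0],
                    end=span[1],
                    is_threshold=False,
                )
            )

    groups = []
    for g in range(n_groups):
        mentions = tuple(
            SnpMention(
                surface=f"rs{g + 1}",
                rsid=f"rs{g + 1}",
                allele=None,
                start=s,
                end=e,
            )
            for gg, (s, e) in mention_spans if gg == g
        )
        groups.append(SnpGroup(rsid=f"rs{g + 1}", mentions=mentions))
    # group order must follow first occurrence, as dedupe_mentions produces
    groups.sort(key=lambda grp: grp.mentions[0].start)
    return groups, values


def oracle_pairing(groups, values):
    """Literal simulation of the pairing procedure, kept independent of the
    implementation: one pass of sequential consumption over a mutable list,
    with edge-to-edge distances recomputed from scratch."""
    pool = sorted([v for v in values if not v.is_threshold], key=lambda v: v.start)
    if not pool or not groups:
        return []
    if len(pool) == 1:
        return [(g.rsid, pool[0]) for g in groups]
    remaining = list(pool)
    pairs = []
    for group in groups:
        if not remaining:
            break
        scored = []
        for v in remaining:
            best = None
            for (s, e) in group.spans:
                if v.start >= e:
                    d, follows = v.start - e, True
                elif v.end <= s:
                    d, follows = s - v.end, False
                else:
                    d, follows = 0, True
                cand = (d, 0 if follows else 1)
                if best is None or cand < best:
                    best = cand
            scored.append((best[0], best[1], v.start, v))
        scored.sort(key=lambda t: t[:3])
        chosen = scored[0][3]
        remaining.remove(chosen)
        pairs.append((group.rsid, chosen))
    return pairs
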