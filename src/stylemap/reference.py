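"""Published corpus accounting for the 15-subreddit mapping study design.

These constants record the per-group cleaned comment counts of the
original one-year Reddit sample (January 2018 - January 2019) and the
yearly counts of the focal r/asktransgender corpus (2011-2019).  They are
inputs to the balanced-sampling arithmetic — given two group sizes, the
pairwise design is fully determined by :func:`stylemap.dissim.balanced_sample_size`
— and let users reason about the published design without access to the
raw data, which is not redistributed here.
"""

from __future__ import annotations

#: Cleaned comment counts per subreddit corpus (one year of comments).
GROUP_COMMENT_COUNTS: dict[str, int] = {
    "Entrepreneur": 91_014,
    "Teachers": 98_797,
    "sales": 25_256,
    "asianamerican": 17_519,
    "islam": 54_495,
    "Christianity": 356_604,
    "Conservative": 134_767,
    "Libertarian": 356_963,
    "Feminism": 15_386,
    "daddit": 17_389,
    "breakingmom": 87_323,
    "relationships": 103_382,
    "asktransgender": 207_527,
    "homeless": 7_748,
    "stopdrinking": 204_928,
}

#: Total cleaned comments across the 15 groups.
TOTAL_COMMENTS: int = sum(GROUP_COMMENT_COUNTS.values())

#: Cleaned yearly comment counts for the focal r/asktransgender corpus.
#: 2019 covers January-October only.
ASKTRANSGENDER_YEARLY_COUNTS: dict[int, int] = {
    2011: 15_620,
    2012: 31_823,
    2013: 51_596,
    2014: 84_294,
    2015: 149_808,
    2016: 183_092,
    2017: 201_570,
    2018: 207_589,
    2019: 177_139,
}
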