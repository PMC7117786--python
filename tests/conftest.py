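from fractions import Fraction

import pytest

from zdgames import (build_double_control, iterated_prisoners_dilemma,
                     rock_paper_scissors, tit_for_tat, two_relation_game)


@pytest.fixture
def ipd():
    return iterated_prisoners_dilemma()


@pytest.fixture
def tft(ipd):
    return tit_for_tat(ipd, 0)


@pytest.fixture
def rps():
    return rock_paper_scissors()


@pytest.fixture
def trg():
    return two_relation_game(1, 2)


DOUBLE_CONTROL_PARAMS = dict(
    r1=1, r2=2, p=Fraction(1, 2), q=Fraction(1, 4),
    p_prime=Fraction(1, 4), q_prime=Fraction(1, 2))


@pytest.fixture
def double_control():
    return build_double_control(**DOUBLE_CONTROL_PARAMS)
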