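"""Amino-acid substitution model constants.

Exchangeabilities and stationary frequencies of the LG empirical model
(Le & Gascuel 2008), in the standard ARNDCQEGHILKMFPSTWYV residue order.
"""

import numpy as np

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

LG_FREQS = np.array([
0.0790659, 0.0559409, 0.041977, 0.0530519, 0.012937, 0.040767, 0.0715859, 0.0573369, 0.022355, 0.0621569, 0.0990809, 0.0645999, 0.022951, 0.042302, 0.04404, 0.0611969, 0.0532869, 0.012066, 0.034155, 0.0691469])

# symmetric exchangeability matrix, zero diagonal
LG_EXCH = np.array([
    [0, 0.425093, 0.276818, 0.395144, 2.48908, 0.969894, 1.03855, 2.06604, 0.358858, 0.14983, 0.395337, 0.536518, 1.12403, 0.253701, 1.17765, 4.72718, 2.1395, 0.180717, 0.218959, 2.54787],
    [0.425093, 0, 0.751878, 0.123954, 0.534551, 2.80791, 0.36397, 0.390192, 2.4266, 0.126991, 0.301848, 6.32607, 0.484133, 0.052722, 0.332533, 0.858151, 0.578987, 0.593607, 0.31444, 0.170887],
    [0.276818, 0.751878, 0, 5.07615, 0.528768, 1.69575, 0.541712, 1.43765, 4.50924, 0.191503, 0.068427, 2.14508, 0.371004, 0.089525, 0.161787, 4.00836, 2.00068, 0.045376, 0.612025, 0.083688],
    [0.395144, 0.123954, 5.07615, 0, 0.062556, 0.523386, 5.24387, 0.844926, 0.927114, 0.01069, 0.015076, 0.282959, 0.025548, 0.017416, 0.394456, 1.24028, 0.42586, 0.02989, 0.135107, 0.037967],
    [2.48908, 0.534551, 0.528768, 0.062556, 0, 0.084808, 0.003499, 0.569265, 0.640543, 0.320627, 0.594007, 0.013266, 0.89368, 1.10525, 0.075382, 2.78448, 1.14348, 0.670128, 1.16553, 1.95929],
    [0.969894, 2.80791, 1.69575, 0.523386, 0.084808, 0, 4.12859, 0.267959, 4.81351, 0.072854, 0.582457, 3.23429, 1.67257, 0.035855, 0.624294, 1.22383, 1.08014, 0.236199, 0.257336, 0.210332],
    [1.03855, 0.36397, 0.541712, 5.24387, 0.003499, 4.12859, 0, 0.348847, 0.423881, 0.044265, 0.069673, 1.80718, 0.173735, 0.018811, 0.419409, 0.611973, 0.604545, 0.077852, 0.120037, 0.245034],
    [2.06604, 0.390192, 1.43765, 0.844926, 0.569265, 0.267959, 0.348847, 0, 0.311484, 0.008705, 0.044261, 0.296636, 0.139538, 0.089586, 0.196961, 1.73999, 0.129836, 0.268491, 0.054679, 0.076701],
    [0.358858, 2.4266, 4.50924, 0.927114, 0.640543, 4.81351, 0.423881, 0.311484, 0, 0.108882, 0.366317, 0.697264, 0.442472, 0.682139, 0.508851, 0.990012, 0.584262, 0.597054, 5.30683, 0.119013],
    [0.14983, 0.126991, 0.191503, 0.01069, 0.320627, 0.072854, 0.044265, 0.008705, 0.108882, 0, 4.14507, 0.159069, 4.27361, 1.11273, 0.078281, 0.064105, 1.03374, 0.11166, 0.232523, 10.6491],
    [0.395337, 0.301848, 0.068427, 0.015076, 0.594007, 0.582457, 0.069673, 0.044261, 0.366317, 4.14507, 0, 0.1375, 6.31236, 2.59269, 0.24906, 0.182287, 0.302936, 0.619632, 0.299648, 1.70274],
    [0.536518, 6.32607, 2.14508, 0.282959, 0.013266, 3.23429, 1.80718, 0.296636, 0.697264, 0.159069, 0.1375, 0, 0.656604, 0.023918, 0.390322, 0.748683, 1.13686, 0.049906, 0.131932, 0.185202],
    [1.12403, 0.484133, 0.371004, 0.025548, 0.89368, 1.67257, 0.173735, 0.139538, 0.442472, 4.27361, 6.31236, 0.656604, 0, 1.79885, 0.099849, 0.34696, 2.02037, 0.696175, 0.481306, 1.89872],
    [0.253701, 0.052722, 0.089525, 0.017416, 1.10525, 0.035855, 0.018811, 0.089586, 0.682139, 1.11273, 2.59269, 0.023918, 1.79885, 0, 0.094464, 0.361819, 0.165001, 2.45712, 7.8039, 0.654683],
    [1.17765, 0.332533, 0.161787, 0.394456, 0.075382, 0.624294, 0.419409, 0.196961, 0.508851, 0.078281, 0.24906, 0.390322, 0.099849, 0.094464, 0, 1.33813, 0.571468, 0.095131, 0.089613, 0.296501],
    [4.72718, 0.858151, 4.00836, 1.24028, 2.78448, 1.22383, 0.611973, 1.73999, 0.990012, 0.064105, 0.182287, 0.748683, 0.34696, 0.361819, 1.33813, 0, 6.47228, 0.248862, 0.400547, 0.098369],
    [2.1395, 0.578987, 2.00068, 0.42586, 1.14348, 1.08014, 0.604545, 0.129836, 0.584262, 1.03374, 0.302936, 1.13686, 2.02037, 0.165001, 0.571468, 6.47228, 0, 0.140825, 0.245841, 2.18816],
    [0.180717, 0.593607, 0.045376, 0.02989, 0.670128, 0.236199, 0.077852, 0.268491, 0.597054, 0.11166, 0.619632, 0.049906, 0.696175, 2.45712, 0.095131, 0.248862, 0.140825, 0, 3.15182, 0.18951],
    [0.218959, 0.31444, 0.612025, 0.135107, 1.16553, 0.257336, 0.120037, 0.054679, 5.30683, 0.232523, 0.299648, 0.131932, 0.481306, 7.8039, 0.089613, 0.400547, 0.245841, 3.15182, 0, 0.249313],
    [2.54787, 0.170887, 0.083688, 0.037967, 1.95929, 0.210332, 0.245034, 0.076701, 0.119013, 10.6491, 1.70274, 0.185202, 1.89872, 0.654683, 0.296501, 0.098369, 2.18816, 0.18951, 0.249313, 0],
])
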