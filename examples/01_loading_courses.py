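"""Loading courses: the hypotheses a fixed-links model encodes.

A loading course is the ordered vector of fixed factor loadings across
the repeated-measures conditions.  The constant course (all ones)
represents processes untouched by the manipulation; the monotone and
inverted-u courses represent processes scaling with task demand.
"""

from fixedlinks import make_course

for name in ("constant", "linear", "quadratic", "logarithmic", "inverted_u"):
    course = make_course(name, 5)
    print(f"{name:12s} {course.values}")

# the inverted-u series comes from the parabola f(x) = (-x^2 + 100)/100
# evaluated at x = -8, -4.5, -1, 2.5, 6: it rises while demand grows
# within capacity and falls once capacity is exceeded
course = make_course("inverted_u", 5, params={"x": (-8, -4.5, -1, 2.5, 6)})
print("\ninverted-u from its parabola:", course.values)
print("peak condition:", course.values.index(max(course.values)) + 1)
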