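"""Packaged everyday-category word lists used by the evaluation harnesses.

Three intuitive semantic categories (fruits, animals, colors) of common
English nouns.  They drive the category-classification fixtures: a simulated
stream built from these lists (one topic per category) yields a similarity
matrix whose rows cluster by category.
"""

FRUITS = (
    "apple", "banana", "blackberry", "blueberry", "cherry", "coconut", "grape",
    "kiwi", "lemon", "lime", "mango", "melon", "watermelon", "orange",
    "tangerine", "papaya", "passion fruit", "peach", "pear", "pineapple",
    "pomelo", "raspberry", "strawberry",
)

ANIMALS = (
    "bull", "cow", "chicken", "donkey", "goat", "horse", "pig", "rabbit",
    "sheep", "dolphin", "shark", "octopus", "turtle", "bird", "eagle", "mouse",
    "owl", "bear", "bat", "dog", "cat", "fly", "ant", "tiger",
)

COLORS = (
    "blue", "green", "red", "yellow", "orange", "black", "white", "pink",
    "brown", "fuchsia", "grey", "purple", "violet", "golden",
)

CATEGORIES = {"fruits": FRUITS, "animals": ANIMALS, "colors": COLORS}
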