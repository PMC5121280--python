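>QLQ_seed_01 synthetic seed alignment sequence
QQQLQLQELYPNQAVRFSPEPLQALRAQLLAFQLGQRGQP
>QLQ_seed_02 synthetic seed alignment sequence
QEQLQLQPIYPQQAVYFSPEQLSALRAQILAFQLLQRSRP
>QLQ_seed_03 synthetic seed alignment sequence
QQQLQRQLLYPQQAVRFSPSQLQALNAQIGAFQLLQRDQP
>QLQ_seed_04 synthetic seed alignment sequence
QQQLQPQELVPQQAGRFSPEQLQALRAQILAFQWLQRGQP
>QLQ_seed_05 synthetic seed alignment sequence
QQQLQLQELYPYQAVRFSPMQLQALRAQILAFQLLQRGQP
>QLQ_seed_06 synthetic seed alignment sequence
VQQLELQELYPQQAVRFSPEALYALRAQILAFQLLQRGQP
>QLQ_seed_07 synthetic seed alignment sequence
QQQLQLQEEYPQQAVRFVREALQFLTADYFAGQLLQRGVP
>QLQ_seed_08 synthetic seed alignment sequence
QQQLQLQELYPYQAVRFSPEQVLALRAQLLAFQLLQNGQP
>QLQ_seed_09 synthetic seed alignment sequence
LQQWQLQELYPQIAVRFSPEQGQHLRAEILAFQPLQRGQP
>QLQ_seed_10 synthetic seed alignment sequence
QQQLTLQLLYPQQAVRFQIEQLAALEAQILAFQQLQRGQP
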