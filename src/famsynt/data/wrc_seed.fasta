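>WRC_seed_01 synthetic seed alignment sequence
GRCRRTDGKKWDESRDVVAGQKYCIRHMHRGRNRSRKPVE
>WRC_seed_02 synthetic seed alignment sequence
GRCRRCDGKKWRCSRDVVPGQKYCDRHMHRGRNRSRKPVE
>WRC_seed_03 synthetic seed alignment sequence
IRCRLTDGKKWRCSRDVKPGQKYCERHMHRGQNRSRKPDP
>WRC_seed_04 synthetic seed alignment sequence
GRCRRTDGKKDRCSRDVVPGQKYCEVHMHRGRNRSRKPVE
>WRC_seed_05 synthetic seed alignment sequence
GRCRRTDGKKTNCSRDVQPGQRYCERGLQRGRNRMRKPVE
>WRC_seed_06 synthetic seed alignment sequence
GRCRCTDGKKWRVWRDVVPGQKYCERHMHRGKNRSRKPVE
>WRC_seed_07 synthetic seed alignment sequence
GSCRWTNGKKWRCSRNVVPFQKYCERHMHVGFNRSRKPVE
>WRC_seed_08 synthetic seed alignment sequence
GRCRRTDGCKERCSRDVVPGQKYSFCHMHTGRNRSRKKVE
>WRC_seed_09 synthetic seed alignment sequence
GRCVRTLFKKERCSRDVQPGKAYCERHMSRGRNRSRYDPE
>WRC_seed_10 synthetic seed alignment sequence
GRCRRFDGKKCRCSRDVVPGQFYCERHMHEGRNRSRKIVE
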