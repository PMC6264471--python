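>P05814|beta-casein signal=15 form=mature
RETIESLSSSEESITEYKQKVEKVKHEDQQQGEDEHQDKIYPSFQPQPLIYPFVEPIPYG
FLPQNILPLAQPAVVLPVPQPEIMEVPKAKDTVYTKGRVMPVLKSPTIPFFDPQIPKLTD
LENLHLPLPLLQPLMQQVPQPIPQTLALPPQPLWSVPQPKVLPIPQQVVPYPQRAVPVQA
LLLNQELLLNPTHQIYPVTQPLAPVHNPISV
>P47710|alpha-s1-casein signal=15 form=mature
RPKLPLRYPERLQNPSESSEPIPLESREEYMNGMNRQRNILREKQTDEIKDTRNESTQNC
VVAEPEKMESSISSSSEEMSLSKCAEQFCRLNEYNQLQLQAAHAQEQIRRMNENSHVQVP
FQQLNQLAAYPYAVWYYPQVMQYVPFPPFSDISNPTAHENYEKNNVMLQW
>P07498|kappa-casein signal=20 form=mature
EVQNQKQPACHENDERPFYQKTAPYVPMYYVPNSYPYYGTNLYQRRPAIAINNPYVPRTY
YANPAVVRPHAQIPQRQYLPNSHPPTVVRRPNLHPSFIAIPPKKIQDKIIIPTINTIATV
EPTPAPATEPTVDSVVTPEAFSESIITSTPETTTVAVTPPTA
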