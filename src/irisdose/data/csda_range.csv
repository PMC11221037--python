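material,energy_MeV,csda_g_cm2
water,1.00000000e-02,2.52000000e-04
water,1.18290872e-02,3.39018220e-04
water,1.39927303e-02,4.56084737e-04
water,1.65521226e-02,6.13575539e-04
water,1.95796501e-02,8.25449553e-04
water,2.31609388e-02,1.11040071e-03
water,2.73972764e-02,1.49370247e-03
water,3.24084770e-02,2.00931706e-03
water,3.83362699e-02,2.70291782e-03
water,4.53483078e-02,3.63594423e-03
water,5.36429086e-02,4.87818690e-03
water,6.34546641e-02,6.52097238e-03
water,7.50610753e-02,8.71698475e-03
water,8.87904002e-02,1.16525295e-02
water,1.05030938e-01,1.55186675e-02
water,1.24242012e-01,2.04816730e-02
water,1.46966959e-01,2.70318910e-02
water,1.73848497e-01,3.56769260e-02
water,2.05646902e-01,4.69491613e-02
water,2.43261513e-01,6.08798344e-02
water,2.87756164e-01,7.89439924e-02
water,3.40389275e-01,1.01123191e-01
water,4.02649440e-01,1.29011780e-01
water,4.76297532e-01,1.64591715e-01
water,5.63416502e-01,2.05477943e-01
water,6.66470291e-01,2.54267414e-01
water,7.88373516e-01,3.17404387e-01
water,9.32573904e-01,3.97651507e-01
water,1.10314980e+00,4.90813999e-01
water,1.30492551e+00,5.99413738e-01
water,1.54360776e+00,7.30727706e-01
water,1.82594708e+00,8.83055932e-01
water,2.15992871e+00,1.06298370e+00
water,2.55499850e+00,1.27367835e+00
water,3.02232999e+00,1.52562471e+00
water,3.57514049e+00,1.81422675e+00
water,4.22906485e+00,2.15444237e+00
water,5.00259767e+00,2.55130578e+00
water,5.91761639e+00,3.01069180e+00
water,7.00000000e+00,3.54500000e+00
lung,1.00000000e-02,2.52000000e-04
lung,1.18290872e-02,3.39018220e-04
lung,1.39927303e-02,4.56084737e-04
lung,1.65521226e-02,6.13575539e-04
lung,1.95796501e-02,8.25449553e-04
lung,2.31609388e-02,1.11040071e-03
lung,2.73972764e-02,1.49370247e-03
lung,3.24084770e-02,2.00931706e-03
lung,3.83362699e-02,2.70291782e-03
lung,4.53483078e-02,3.63594423e-03
lung,5.36429086e-02,4.87818690e-03
lung,6.34546641e-02,6.52097238e-03
lung,7.50610753e-02,8.71698475e-03
lung,8.87904002e-02,1.16525295e-02
lung,1.05030938e-01,1.55186675e-02
lung,1.24242012e-01,2.04816730e-02
lung,1.46966959e-01,2.70318910e-02
lung,1.73848497e-01,3.56769260e-02
lung,2.05646902e-01,4.69491613e-02
lung,2.43261513e-01,6.08798344e-02
lung,2.87756164e-01,7.89439924e-02
lung,3.40389275e-01,1.01123191e-01
lung,4.02649440e-01,1.29011780e-01
lung,4.76297532e-01,1.64591715e-01
lung,5.63416502e-01,2.05477943e-01
lung,6.66470291e-01,2.54267414e-01
lung,7.88373516e-01,3.17404387e-01
lung,9.32573904e-01,3.97651507e-01
lung,1.10314980e+00,4.90813999e-01
lung,1.30492551e+00,5.99413738e-01
lung,1.54360776e+00,7.30727706e-01
lung,1.82594708e+00,8.83055932e-01
lung,2.15992871e+00,1.06298370e+00
lung,2.55499850e+00,1.27367835e+00
lung,3.02232999e+00,1.52562471e+00
lung,3.57514049e+00,1.81422675e+00
lung,4.22906485e+00,2.15444237e+00
lung,5.00259767e+00,2.55130578e+00
lung,5.91761639e+00,3.01069180e+00
lung,7.00000000e+00,3.54500000e+00
bone,1.00000000e-02,2.52000000e-04
bone,1.18290872e-02,3.39018220e-04
bone,1.39927303e-02,4.56084737e-04
bone,1.65521226e-02,6.13575539e-04
bone,1.95796501e-02,8.25449553e-04
bone,2.31609388e-02,1.11040071e-03
bone,2.73972764e-02,1.49370247e-03
bone,3.24084770e-02,2.00931706e-03
bone,3.83362699e-02,2.70291782e-03
bone,4.53483078e-02,3.63594423e-03
bone,5.36429086e-02,4.87818690e-03
bone,6.34546641e-02,6.52097238e-03
bone,7.50610753e-02,8.71698475e-03
bone,8.87904002e-02,1.16525295e-02
bone,1.05030938e-01,1.55186675e-02
bone,1.24242012e-01,2.04816730e-02
bone,1.46966959e-01,2.70318910e-02
bone,1.73848497e-01,3.56769260e-02
bone,2.05646902e-01,4.69491613e-02
bone,2.43261513e-01,6.08798344e-02
bone,2.87756164e-01,7.89439924e-02
bone,3.40389275e-01,1.01123191e-01
bone,4.02649440e-01,1.29011780e-01
bone,4.76297532e-01,1.64591715e-01
bone,5.63416502e-01,2.05477943e-01
bone,6.66470291e-01,2.54267414e-01
bone,7.88373516e-01,3.17404387e-01
bone,9.32573904e-01,3.97651507e-01
bone,1.10314980e+00,4.90813999e-01
bone,1.30492551e+00,5.99413738e-01
bone,1.54360776e+00,7.30727706e-01
bone,1.82594708e+00,8.83055932e-01
bone,2.15992871e+00,1.06298370e+00
bone,2.55499850e+00,1.27367835e+00
bone,3.02232999e+00,1.52562471e+00
bone,3.57514049e+00,1.81422675e+00
bone,4.22906485e+00,2.15444237e+00
bone,5.00259767e+00,2.55130578e+00
bone,5.91761639e+00,3.01069180e+00
bone,7.00000000e+00,3.54500000e+00
air,1.00000000e-02,2.52000000e-04
air,1.18290872e-02,3.39018220e-04
air,1.39927303e-02,4.56084737e-04
air,1.65521226e-02,6.13575539e-04
air,1.95796501e-02,8.25449553e-04
air,2.31609388e-02,1.11040071e-03
air,2.73972764e-02,1.49370247e-03
air,3.24084770e-02,2.00931706e-03
air,3.83362699e-02,2.70291782e-03
air,4.53483078e-02,3.63594423e-03
air,5.36429086e-02,4.87818690e-03
air,6.34546641e-02,6.52097238e-03
air,7.50610753e-02,8.71698475e-03
air,8.87904002e-02,1.16525295e-02
air,1.05030938e-01,1.55186675e-02
air,1.24242012e-01,2.04816730e-02
air,1.46966959e-01,2.70318910e-02
air,1.73848497e-01,3.56769260e-02
air,2.05646902e-01,4.69491613e-02
air,2.43261513e-01,6.08798344e-02
air,2.87756164e-01,7.89439924e-02
air,3.40389275e-01,1.01123191e-01
air,4.02649440e-01,1.29011780e-01
air,4.76297532e-01,1.64591715e-01
air,5.63416502e-01,2.05477943e-01
air,6.66470291e-01,2.54267414e-01
air,7.88373516e-01,3.17404387e-01
air,9.32573904e-01,3.97651507e-01
air,1.10314980e+00,4.90813999e-01
air,1.30492551e+00,5.99413738e-01
air,1.54360776e+00,7.30727706e-01
air,1.82594708e+00,8.83055932e-01
air,2.15992871e+00,1.06298370e+00
air,2.55499850e+00,1.27367835e+00
air,3.02232999e+00,1.52562471e+00
air,3.57514049e+00,1.81422675e+00
air,4.22906485e+00,2.15444237e+00
air,5.00259767e+00,2.55130578e+00
air,5.91761639e+00,3.01069180e+00
air,7.00000000e+00,3.54500000e+00
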