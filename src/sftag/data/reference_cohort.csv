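id,group,logmar,logcs,ssvep_higher_db,ssvep_lower_db,log_ratio
C1,control,-0.2122,1.84,22.08,7.86,-3.27
C2,control,-0.09,1.64,3.53,2.98,-0.13
C3,control,-0.06,1.94,10.21,9.07,-0.26
C4,control,-0.02,2.11,17.49,10.99,-1.50
C5,control,-0.02,1.85,15.33,8.79,-1.51
C6,control,0.02,1.47,6.53,12.23,1.31
C7,control,0.02,1.80,13.23,14.46,0.28
C8,control,0.02,1.72,10.49,12.98,0.57
C9,control,0.05,1.82,8.71,11.17,0.56
C10,control,0.05,1.82,8.06,13.37,1.22
C11,control,0.06,1.57,13.54,15.11,0.36
AMD12,AMD,0.07,1.65,7.95,10.87,0.67
AMD13,AMD,0.07,1.94,6.26,11.52,1.21
C14,control,0.08,1.77,11.25,9.38,-0.43
C15,control,0.09,1.83,17.87,14.07,-0.88
AMD16,AMD,0.09,1.81,6.37,12.89,1.50
AMD17,AMD,0.11,1.40,5.16,13.86,2.00
C18,control,0.12,1.59,7.80,14.70,1.59
C19,control,0.14,1.69,11.24,9.80,-0.33
AMD20,AMD,0.20,1.78,3.56,11.95,1.93
C21,control,0.23,1.42,9.22,9.84,0.14
AMD22,AMD,0.23,0.82,6.63,13.07,1.48
AMD23,AMD,0.25,1.59,7.62,15.98,1.92
AMD24,AMD,0.28,1.35,3.77,12.67,2.05
AMD25,AMD,0.28,1.31,0.45,13.36,2.97
AMD26,AMD,0.38,1.21,6.06,11.65,1.29
AMD27,AMD,0.39,0.95,8.17,18.76,2.44
AMD28,AMD,0.41,0.90,7.75,13.89,1.41
AMD29,AMD,0.47,0.93,4.14,11.22,1.63
AMD30,AMD,0.53,0.39,7.91,10.66,0.63
AMD31,AMD,0.81,0.20,7.99,16.16,1.88
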